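"""Built-in catalogue of 49 neuroscience meta-analyses.

Each row: (label, n_studies, measure, effect_size, ci_low, ci_high,
significant, subfield).  Measures: "d" = Cohen's d (standardized mean
difference), "or" = odds ratio, "rr" = relative risk.  Effect sizes and
confidence intervals are kept exactly as printed in the source catalogue,
including a handful of internally inconsistent rows (e.g. a negative d with
a ratio-scale CI); ``validate_catalogue`` reports those but never edits
them.  CI bounds are normalized so that ci_low <= ci_high.

The one split publication contributes two records (a cohort arm and a
case-control arm), which is why labels run ma01..ma48 but there are 49
records.  ``APOE_LABEL`` marks the meta-analysis of APOE epsilon-4 and
multiple-sclerosis susceptibility whose pooled odds ratio is exactly 1.00;
its CI is stored at the full precision quoted in the running text
(0.861-1.156) rather than the table's two-decimal rounding.
"""

# Label of the APOE epsilon-4 / multiple sclerosis susceptibility
# meta-analysis (pooled OR exactly 1.00: the canonical null effect).
APOE_LABEL = "ma42"

# Label of the QT-prolongation antipsychotics meta-analysis (OR 0.67,
# CI 0.43-1.04): non-significant, but with a sizeable point estimate.
QT_LABEL = "ma09"

ROWS = (
    ("ma01", 13, "d", -1.11, -1.25, -0.97, True, "psychology"),
    ("ma02", 18, "or", 1.47, 1.22, 1.77, True, "genetic"),
    ("ma03", 6, "d", -1.20, 1.60, 8.00, True, "treatment"),
    ("ma04", 21, "d", 0.41, 0.17, 0.65, True, "neurochemistry"),
    ("ma05", 11, "d", -0.51, 0.83, 1.08, True, "psychology"),
    ("ma06", 56, "d", -0.19, -0.29, -0.10, True, "psychology"),
    ("ma07", 6, "or", 0.98, 0.86, 1.12, False, "genetic"),
    ("ma08", 12, "or", 0.60, 0.52, 0.69, True, "miscellaneous"),
    ("ma09", 11, "or", 0.67, 0.43, 1.04, False, "treatment"),
    ("ma10", 14, "or", 2.12, 1.59, 2.78, True, "psychology"),
    ("ma11", 14, "or", 0.80, 0.70, 0.92, True, "treatment"),
    ("ma12", 4, "or", 1.20, 1.04, 1.40, True, "genetic"),
    ("ma13", 17, "d", -0.59, -0.93, -0.26, True, "neurochemistry"),
    ("ma14", 14, "or", 1.35, 1.06, 1.72, True, "genetic"),
    ("ma15", 13, "d", -0.13, -0.55, 0.29, False, "treatment"),
    ("ma16", 27, "or", 1.13, 1.05, 1.21, True, "genetic"),
    ("ma17", 8, "or", 1.05, 0.92, 1.19, False, "treatment"),
    ("ma18", 12, "or", 1.04, 0.88, 1.22, False, "genetic"),
    ("ma19", 6, "or", 0.89, 0.82, 0.96, True, "genetic"),
    ("ma20", 57, "d", 0.58, 0.51, 0.64, True, "psychology"),
    ("ma21", 5, "rr", 1.67, 1.23, 2.26, True, "treatment"),
    ("ma22", 6, "or", 1.12, 1.00, 1.26, True, "genetic"),
    ("ma23", 14, "d", -0.40, -0.62, -0.19, True, "imaging"),
    ("ma24", 10, "d", -0.51, -0.73, -0.28, True, "psychology"),
    ("ma25", 7, "or", 0.86, 0.79, 0.95, True, "treatment"),
    ("ma26", 36, "or", 1.26, 1.09, 1.46, True, "genetic"),
    ("ma27", 22, "d", 0.92, 0.44, 1.39, True, "treatment"),
    ("ma28", 5, "or", 2.06, 1.33, 3.19, True, "miscellaneous"),
    ("ma29", 8, "d", 0.43, 0.06, 0.80, True, "imaging"),
    ("ma30", 11, "d", 0.89, 0.75, 1.02, True, "psychology"),
    ("ma31", 2, "rr", 1.23, 1.08, 1.52, True, "treatment"),
    ("ma32", 12, "d", 0.15, 0.04, 0.26, True, "neurochemistry"),
    ("ma33", 6, "or", 1.93, 1.55, 2.41, True, "genetic"),
    ("ma34", 4, "d", 1.26, 0.95, 1.57, True, "treatment"),
    ("ma35", 11, "or", 1.98, 1.33, 2.94, True, "imaging"),
    ("ma36", 8, "d", 0.37, 0.20, 0.53, True, "treatment"),
    ("ma37", 24, "or", 0.83, 0.74, 0.93, True, "treatment"),
    ("ma38", 10, "rr", 0.68, 0.60, 0.77, True, "treatment"),
    ("ma39", 53, "d", -0.14, -0.21, -0.07, True, "genetic"),
    ("ma40", 26, "d", -1.41, -1.76, -1.05, True, "psychology"),
    ("ma41", 24, "d", -0.60, -0.83, -0.37, True, "imaging"),
    ("ma42", 20, "or", 1.00, 0.861, 1.156, False, "genetic"),
    ("ma43-cohort", 14, "rr", 1.38, 1.18, 1.61, True, "miscellaneous"),
    ("ma43-case-control", 7, "or", 2.48, 1.93, 3.19, True, "miscellaneous"),
    ("ma44", 3, "d", 0.67, 0.43, 0.92, True, "treatment"),
    ("ma45", 14, "or", 4.98, 3.97, 6.23, True, "genetic"),
    ("ma46", 8, "rr", 1.07, 0.91, 1.27, False, "treatment"),
    ("ma47", 12, "or", 1.27, 1.01, 1.59, True, "genetic"),
    ("ma48", 8, "d", 0.84, 0.18, 1.49, True, "imaging"),
)
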