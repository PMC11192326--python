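"""Published group-level statistics reproduced by the analytic acceptance
suite. Each entry carries the printed paired-t statistic and sample size;
Cohen's d and the one-sided default-prior Bayes factor are recomputed from
those inputs alone (d = t/sqrt(n); BF by quadrature), so agreement checks
the formulas, not the data.
"""

#: (label, t, n, direction, printed_d, printed_bf10)
#: direction is the hypothesized sign of the spider-minus-wheel difference
#: on the amplitude scale ('less' for the negative component, whose effect
#: is a *more negative* amplitude).
REFERENCE_CONTRASTS = [
    ("exp1_N40_FIX", -1.747, 36, "less", -0.291, 1.342),
    ("exp1_P80_FIX", 3.525, 36, "greater", 0.588, 53.470),
    ("exp1_PTP_FIX", 4.547, 36, "greater", 0.758, 764.941),
    ("exp2_N40", -0.403, 35, "less", -0.068, 0.254),
    ("exp2_P100", -0.925, 35, "greater", -0.156, 0.102),
    ("exp2_PTP", 2.334, 35, "greater", 0.394, 3.819),
]

#: printed meta-average peak latencies (ms) and windows of interest:
#: (component, peak, lo, hi)
REFERENCE_WOIS = [
    ("exp1_N40_FIX", "negative", 39.0, 36.0, 42.0),
    ("exp1_P80_FIX", "positive", 80.0, 74.0, 86.0),
    ("exp1_P80_LL", "positive", 88.0, 82.0, 94.0),
    ("exp1_P80_LR", "positive", 86.0, 80.0, 92.0),
    ("exp1_P80_UL", "positive", 90.0, 84.0, 96.0),
    ("exp1_P80_UR", "positive", 101.0, 95.0, 107.0),
    ("exp2_N40", "negative", 45.0, 42.0, 48.0),
    ("exp2_P100", "positive", 105.0, 99.0, 111.0),
]

#: the five per-location positive-component contrasts share one alpha
BONFERRONI_CONTRASTS = 5
BONFERRONI_ALPHA = 0.01
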