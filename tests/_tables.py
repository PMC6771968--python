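"""Published reference values used by the population-value tests.

TABLE_2X2: 35 scenarios of (P(D), alpha, OR) with the cell percentages
and population DN, DS, EV of the dichotomous-outcome calculator.
TABLE_SURV_UNCENSORED: population (DN, DS, EV) for the two-group
exponential model without censoring, HR x alpha grid.
TABLE_SURV_TYPE1: type-I-censored rows (hr, tau, pct_censored, dn, ds,
ev) for the balanced (alpha = 0.5) design; pct_censored is None for the
one cell whose printed censoring percentage is inconsistent with the
analytic value and is therefore not asserted.
"""

import math

INF = math.inf

# scenario, p_d, alpha, odds_ratio, a%, b%, c%, d%, DN, DS, EV
TABLE_2X2 = [
    (1, 0.1, 0.1, 10, 84.1, 5.9, 5.9, 4.1, 0.346, 0.346, 0.120),
    (2, 0.1, 0.5, 10, 48.9, 41.1, 1.1, 8.9, 0.787, 0.087, 0.069),
    (3, 0.1, 0.9, 10, 9.9, 80.1, 0.1, 9.9, 0.878, 0.011, 0.010),
    (4, 0.5, 0.1, 10, 48.9, 1.1, 41.1, 8.9, 0.087, 0.787, 0.069),
    (5, 0.5, 0.5, 10, 38.0, 12.0, 12.0, 38.0, 0.519, 0.519, 0.270),
    (6, 0.5, 0.9, 10, 8.9, 41.1, 1.1, 48.9, 0.787, 0.087, 0.069),
    (7, 0.9, 0.1, 10, 9.9, 0.1, 80.1, 9.9, 0.011, 0.878, 0.010),
    (8, 0.9, 0.5, 10, 8.9, 1.1, 41.1, 48.9, 0.087, 0.787, 0.069),
    (9, 0.9, 0.9, 10, 4.1, 5.9, 5.9, 84.1, 0.346, 0.346, 0.120),
    (10, 0.1, 0.1, 100, 87.4, 2.6, 2.6, 7.4, 0.716, 0.716, 0.513),
    (11, 0.1, 0.5, 100, 49.9, 40.1, 0.1, 9.9, 0.975, 0.108, 0.106),
    (12, 0.1, 0.9, 100, 10.0, 80.0, 0.0, 10.0, 0.988, 0.012, 0.012),
    (13, 0.5, 0.1, 100, 49.9, 0.1, 40.1, 9.9, 0.108, 0.975, 0.106),
    (14, 0.5, 0.5, 100, 45.5, 4.5, 4.5, 45.5, 0.818, 0.818, 0.669),
    (15, 0.5, 0.9, 100, 9.9, 40.1, 0.1, 49.9, 0.975, 0.108, 0.106),
    (16, 0.9, 0.1, 100, 10.0, 0.0, 80.0, 10.0, 0.012, 0.988, 0.012),
    (17, 0.9, 0.5, 100, 9.9, 0.1, 40.1, 49.9, 0.108, 0.975, 0.106),
    (18, 0.9, 0.9, 100, 7.4, 2.6, 2.6, 87.4, 0.716, 0.716, 0.513),
    (19, 0.1, 0.1, 0.1, 5.9, 84.1, 4.1, 5.9, 0.346, 0.346, 0.120),
    (20, 0.1, 0.5, 0.1, 41.1, 48.9, 8.9, 1.1, 0.787, 0.087, 0.069),
    (21, 0.1, 0.9, 0.1, 80.1, 9.9, 9.9, 0.1, 0.878, 0.011, 0.010),
    (22, 0.5, 0.1, 0.1, 1.1, 48.9, 8.9, 41.1, 0.087, 0.787, 0.069),
    (23, 0.5, 0.5, 0.1, 12.0, 38.0, 38.0, 12.0, 0.519, 0.519, 0.270),
    (24, 0.5, 0.9, 0.1, 41.1, 8.9, 48.9, 1.1, 0.787, 0.087, 0.069),
    (25, 0.9, 0.1, 0.1, 0.1, 9.9, 9.9, 80.1, 0.011, 0.878, 0.010),
    (26, 0.9, 0.5, 0.1, 1.1, 8.9, 48.9, 41.1, 0.087, 0.787, 0.069),
    (27, 0.9, 0.9, 0.1, 5.9, 4.1, 84.1, 5.9, 0.346, 0.346, 0.120),
    (28, 0.1, 0.1, 1, 81.0, 9.0, 9.0, 1.0, 0.000, 0.000, 0.000),
    (29, 0.5, 0.5, 1, 25.0, 25.0, 25.0, 25.0, 0.000, 0.000, 0.000),
    (30, 0.5, 0.5, 0, 0.0, 50.0, 50.0, 0.0, 1.000, 1.000, 1.000),
    (31, 0.1, 0.5, INF, 50.0, 40.0, 0.0, 10.0, 1.000, 0.111, 0.111),
    (32, 0.5, 0.5, INF, 50.0, 0.0, 0.0, 50.0, 1.000, 1.000, 1.000),
    (33, 0.9, 0.5, INF, 10.0, 0.0, 40.0, 50.0, 0.111, 1.000, 0.111),
    (34, 0.01, 0.5, 100, 50.0, 49.0, 0.01, 1.0, 0.980, 0.010, 0.010),
    (35, 0.5, 0.01, 100, 50.0, 0.01, 49.0, 1.0, 0.010, 0.980, 0.010),
]

# hr -> {alpha: (dn, ds, ev)}
TABLE_SURV_UNCENSORED = {
    1: {0.1: (0.00, 0.00, 0.00), 0.5: (0.00, 0.00, 0.00), 0.9: (0.00, 0.00, 0.00)},
    2: {0.1: (0.05, 0.47, 0.02), 0.5: (0.22, 0.31, 0.05), 0.9: (0.36, 0.08, 0.02)},
    10: {0.1: (0.16, 0.85, 0.12), 0.5: (0.55, 0.61, 0.32), 0.9: (0.80, 0.21, 0.12)},
    100: {0.1: (0.24, 0.94, 0.17), 0.5: (0.68, 0.68, 0.48), 0.9: (0.93, 0.25, 0.17)},
}

# (hr, tau, pct_censored_or_None, dn, ds, ev), balanced factor
TABLE_SURV_TYPE1 = [
    (1, 1.64, 20, 0.00, 0.00, 0.00),
    (1, 0.22, 80, 0.00, 0.00, 0.00),
    (2, 2.26, None, 0.25, 0.20, 0.05),  # printed 23%, analytic ~21.4%
    (2, 0.30, 80, 0.32, 0.04, 0.02),
    (10, 4.90, 31, 0.71, 0.44, 0.34),
    (10, 0.43, 81, 0.80, 0.09, 0.09),
    (100, 15.30, 43, 0.96, 0.45, 0.53),
    (100, 0.47, 81, 0.98, 0.11, 0.14),
]
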