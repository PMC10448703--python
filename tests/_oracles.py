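"""Independent reference computations used by unit and acceptance tests.

These deliberately avoid the code paths (statsmodels/pingouin wrappers) they
check: ANOVA F statistics come from explicit design-matrix / sums-of-squares
algebra, and the JZS Bayes factor from direct numerical integration of the
marginal likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate


def between_2x2_type3_oracle(scores, levels_a, levels_b):
    """Type III F statistics for a 2x2 between design via effect coding.

    With +-1 effect coding each term has one df, so its Type III sum of
    squares is beta_j^2 / [(X'X)^-1]_jj from the full-model normal equations.
    """
    y = np.asarray(scores, dtype=float)
    a = np.where(np.asarray(levels_a) == sorted(set(levels_a))[0], 1.0, -1.0)
    b = np.where(np.asarray(levels_b) == sorted(set(levels_b))[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), a, b, a * b])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dfe = len(y) - 4
    mse = resid @ resid / dfe
    c = np.linalg.inv(X.T @ X)
    out = {}
    for name, j in (("main_a", 1), ("main_b", 2), ("interaction", 3)):
        ss = beta[j] ** 2 / c[j, j]
        out[name] = ss / mse
    return out


def mixed_2x2_oracle(frame, within_col="a", between_col="b"):
    """Classic univariate mixed-ANOVA F statistics (balanced groups).

    ``frame`` has columns subject, score, and the two factor columns; every
    subject contributes one score per within level.
    """
    gm = frame["score"].mean()
    subj_means = frame.groupby("subject")["score"].mean()
    n_subj = len(subj_means)
    ss_between_subj = 2.0 * ((subj_means - gm) ** 2).sum()

    grp = frame.groupby(between_col)["score"]
    grp_sizes = frame.groupby(between_col)["subject"].nunique()
    ss_b = sum(2.0 * grp_sizes[g] * (grp.mean()[g] - gm) ** 2 for g in grp.mean().index)
    ss_subj_within = ss_between_subj - ss_b
    df_sw = n_subj - 2

    a_means = frame.groupby(within_col)["score"].mean()
    ss_a = sum(n_subj * (a_means[lvl] - gm) ** 2 for lvl in a_means.index)
    cell = frame.groupby([within_col, between_col])["score"].mean()
    b_means = frame.groupby(between_col)["score"].mean()
    ss_ab = 0.0
    for (la, lb), m in cell.items():
        n_g = grp_sizes[lb]
        ss_ab += n_g * (m - a_means[la] - b_means[lb] + gm) ** 2

    within_dev = frame["score"] - frame["subject"].map(subj_means)
    ss_within_total = (within_dev**2).sum()
    ss_err = ss_within_total - ss_a - ss_ab
    df_err = n_subj - 2
    return {
        "within": (ss_a / 1) / (ss_err / df_err),
        "between": (ss_b / 1) / (ss_subj_within / df_sw),
        "interaction": (ss_ab / 1) / (ss_err / df_err),
    }


def jzs_bf10_oracle(t, nx, ny=None, paired=False, r=0.707):
    """JZS Bayes factor by numerical integration of the marginal likelihood."""
    if ny is None or paired:
        n, df = nx, nx - 1
    else:
        n, df = nx * ny / (nx + ny), nx + ny - 2

    def integrand(g):
        return (
            (1 + n * g * r**2) ** (-0.5)
            * (1 + t**2 / ((1 + n * g * r**2) * df)) ** (-(df + 1) / 2)
            * (2 * np.pi) ** (-0.5)
            * g ** (-1.5)
            * np.exp(-1 / (2 * g))
        )

    numerator, _ = integrate.quad(integrand, 0, np.inf)
    denominator = (1 + t**2 / df) ** (-(df + 1) / 2)
    return numerator / denominator
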