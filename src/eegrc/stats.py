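"""Regional summaries, asymmetry index and between-group statistics.

Per-channel metrics (relative band power, fractal dimension, DFA exponent)
are summarised as the 19-channel global mean, the rostral and caudal
7-channel means, and the rostrocaudal asymmetry (rostral minus caudal;
positive = rostral dominance).  Group comparisons use one-way ANOVA with
Tukey HSD post-hocs (pairwise pooled t and Cohen's d reported alongside),
Pillai's-trace MANOVA for the joint band-power profile, Mann-Whitney U for
non-normal data, and channelwise pooled-t maps with Benjamini-Hochberg FDR
correction across the 19 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from .io import Montage, standard_montage


@dataclass
class RegionalSummary:
    """Regional means of one per-channel metric for one subject."""

    subject_id: str
    metric: str
    global_mean: float
    rostral_mean: float
    caudal_mean: float

    @property
    def asymmetry(self) -> float:
        """Rostral minus caudal mean; positive = rostral dominance."""
        return self.rostral_mean - self.caudal_mean


@dataclass
class StatResult:
    """One test outcome (t, F, U or Pillai's trace)."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    effect_size: float | None = None   # Cohen's d or r^2
    effect_name: str = ""
    comparison: tuple = ()

    def as_row(self) -> dict:
        return {
            "test": self.test, "comparison": ":".join(self.comparison),
            "statistic": self.statistic,
            "df": ",".join(f"{d:g}" for d in self.df),
            "p": self.p_value, self.effect_name or "effect": self.effect_size,
        }


@dataclass
class ChannelTMap:
    """Per-channel pooled-t comparison with BH-FDR adjusted p-values."""

    channels: list[str]
    t_values: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    comparison: tuple
    alpha_level: float = 0.05
    metric: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": self.channels, "t": self.t_values, "p": self.p_raw,
            "p_fdr": self.p_fdr, "significant": self.significant,
        })


def regional_summary(per_channel: dict, montage: Montage | None = None,
                     subject_id: str = "", metric: str = "") -> RegionalSummary:
    """Global, rostral and caudal means of a channel -> value map."""
    montage = montage or standard_montage()
    missing = [c for c in montage.all19 if c not in per_channel]
    if missing:
        raise ValueError(f"missing channels: {', '.join(missing)}")
    vals = {c: float(per_channel[c]) for c in montage.all19}
    return RegionalSummary(
        subject_id=subject_id, metric=metric,
        global_mean=float(np.mean([vals[c] for c in montage.all19])),
        rostral_mean=float(np.mean([vals[c] for c in montage.rostral])),
        caudal_mean=float(np.mean([vals[c] for c in montage.caudal])),
    )


def cohens_d(group1, group2) -> float:
    """Standardised mean difference with the pooled standard deviation.

    Sign follows mean(group1) - mean(group2).
    """
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                  / (n1 + n2 - 2))
    if pooled_var == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def one_way_anova(groups: dict) -> StatResult:
    """One-way ANOVA over labelled groups; effect size r^2 = SSb/SStot."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_total = ((allv - grand) ** 2).sum()
    ss_within = ss_total - ss_between
    df_b = len(arrays) - 1
    df_w = allv.size - len(arrays)
    if ss_total == 0:
        return StatResult("anova", float("nan"), (df_b, df_w), 1.0, 0.0,
                          "r2", tuple(labels))
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    p = float(ss.f.sf(f, df_b, df_w))
    return StatResult("anova", float(f), (df_b, df_w), p,
                      float(ss_between / ss_total), "r2", tuple(labels))


def pooled_t(group1, group2) -> tuple[float, int, float]:
    """Two-sample pooled-variance t: (t, df, two-sided p)."""
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    t, p = ss.ttest_ind(x, y, equal_var=True)
    return float(t), x.size + y.size - 2, float(p)


def tukey_hsd(groups: dict) -> list[StatResult]:
    """Tukey HSD pairwise comparisons.

    Adjusted p-values come from the studentized-range distribution (via
    ``scipy.stats.tukey_hsd``); the pairwise pooled t (with per-pair
    n1+n2-2 df) and Cohen's d are reported alongside, since these are the
    quantities conventionally printed next to the adjusted p.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    res = ss.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            t, df, _ = pooled_t(arrays[i], arrays[j])
            out.append(StatResult(
                test="tukey_hsd", statistic=t, df=(df,),
                p_value=float(res.pvalue[i, j]),
                effect_size=cohens_d(arrays[i], arrays[j]),
                effect_name="cohens_d", comparison=(labels[i], labels[j]),
            ))
    return out


def pillai_manova(groups: dict) -> StatResult:
    """One-way MANOVA: Pillai's trace with its standard F approximation.

    ``groups`` maps label -> (n_i, p) observation matrix.  Pillai's trace
    V = sum(lambda / (1 + lambda)) over the eigenvalues of W^-1 B, where B
    and W are the between- and within-group SSCP matrices.
    """
    labels = list(groups)
    mats = [np.atleast_2d(np.asarray(groups[g], float)) for g in labels]
    k = len(mats)
    if k < 2:
        raise ValueError("need >= 2 groups")
    p = mats[0].shape[1]
    if p < 2 or any(m.shape[1] != p for m in mats):
        raise ValueError("observations must share dimension >= 2")
    n_total = sum(m.shape[0] for m in mats)
    if n_total <= p + k:
        raise ValueError("too few observations for the dimension")
    grand = np.vstack(mats).mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for m in mats:
        d = m.mean(axis=0) - grand
        B += m.shape[0] * np.outer(d, d)
        c = m - m.mean(axis=0)
        W += c.T @ c
    if np.linalg.matrix_rank(W) < p:
        raise np.linalg.LinAlgError("singular within-group covariance")
    eig = np.linalg.eigvals(np.linalg.solve(W, B))
    eig = np.clip(eig.real, 0, None)
    v = float(np.sum(eig / (1.0 + eig)))
    q = k - 1
    s = min(p, q)
    m_par = (abs(p - q) - 1) / 2.0
    n_par = (n_total - k - p - 1) / 2.0
    df1 = s * (2 * m_par + s + 1)
    df2 = s * (2 * n_par + s + 1)
    f = (df2 / df1) * v / (s - v)
    return StatResult("pillai_manova", v, (df1, df2),
                      float(ss.f.sf(f, df1, df2)), float(f), "F",
                      tuple(labels))


def mann_whitney_u(group1, group2) -> StatResult:
    """Mann-Whitney U (min-of-U1/U2 convention).

    Exact p for small tie-free samples, otherwise the tie-corrected normal
    approximation (scipy's automatic policy).
    """
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    d = cohens_d(x, y) if x.size > 1 and y.size > 1 else None
    return StatResult("mann_whitney_u", u, (x.size, y.size),
                      float(res.pvalue), d, "cohens_d")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def channelwise_t_map(metric: pd.DataFrame, labels: pd.Series,
                      comparison: tuple, alpha_level: float = 0.05,
                      metric_name: str = "") -> ChannelTMap:
    """Per-channel pooled t between two groups with BH-FDR over channels.

    ``metric`` is subjects x channels; ``labels`` maps subject -> group.
    FDR correction is applied within this comparison's 19-channel family.
    """
    g1, g2 = comparison
    a = metric.loc[labels[labels == g1].index]
    b = metric.loc[labels[labels == g2].index]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    tvals, pvals = ss.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0,
                                equal_var=True)
    p_fdr = bh_adjust(pvals)
    return ChannelTMap(
        channels=list(metric.columns), t_values=np.asarray(tvals),
        p_raw=np.asarray(pvals), p_fdr=p_fdr,
        significant=p_fdr < alpha_level, comparison=comparison,
        alpha_level=alpha_level, metric=metric_name,
    )


def normality_diagnostic(values) -> StatResult:
    """D'Agostino-Pearson omnibus normality test (reported, not acted on)."""
    stat, p = ss.normaltest(np.asarray(values, float))
    return StatResult("dagostino_pearson", float(stat), (2,), float(p))
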