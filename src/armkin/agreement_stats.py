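"""Repeated-measures Bland-Altman agreement, RMSE, and comparison ANOVAs.

For each difference set (all per-frame angle differences between a test method
and the reference, grouped by participant) a one-way ANOVA with participant as
the factor partitions the variance into between-participant and
within-participant (residual) components:

    MS_participant = SS_between / (k - 1)
    MS_residual    = SS_within / (N - k)
    var_between    = max(0, (MS_participant - MS_residual) / n_bar)
    var_total      = var_between + MS_residual
    SD             = sqrt(var_total)

with ``n_bar = N / k`` the average number of observations per participant.
The bias is the grand mean of the pooled differences, the 95% limits of
agreement are ``bias +/- 1.96 SD``, and the RMSE is ``sqrt(MS_residual)``
(within-participant variability).

Method and camera-placement comparisons are one-way ANOVAs on the per-set
RMSE values, reported with partial eta-squared and Cohen's
``f = sqrt(eta2p / (1 - eta2p))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import ParameterError

__all__ = [
    "DifferenceSet",
    "AgreementResult",
    "AnovaResult",
    "variance_partition",
    "bland_altman",
    "anova_oneway",
    "compare_methods",
    "compare_planes",
    "simulate_difference_set",
]

LOA_FACTOR = 1.96  # 95% limits of agreement


@dataclass
class DifferenceSet:
    """Per-participant angle differences for one (method, placement, movement,
    angle set) combination."""

    labels: dict = field(default_factory=dict)
    data: dict[str, np.ndarray] = field(default_factory=dict)  # participant -> diffs

    def __post_init__(self):
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        if len(self.data) < 2:
            raise ParameterError("a difference set needs at least 2 participants")
        for pid, v in self.data.items():
            if v.ndim != 1 or len(v) < 2:
                raise ParameterError(
                    f"participant {pid!r} needs at least 2 observations"
                )

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def n_obs(self) -> int:
        return sum(len(v) for v in self.data.values())

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.data[k] for k in self.data])


@dataclass
class AgreementResult:
    bias: float
    ms_participant: float
    ms_residual: float
    var_between: float
    var_total: float
    sd: float
    loa_lower: float
    loa_upper: float
    rmse: float
    n_participants: int
    n_obs: int
    labels: dict = field(default_factory=dict)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    partial_eta_squared: float
    cohens_f: float
    df_group: int
    df_error: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def variance_partition(ds: DifferenceSet, nbar_mode: str = "mean") -> dict:
    """One-way variance decomposition with participant as the factor.

    ``nbar_mode`` selects the per-participant observation count used to
    convert the mean-square difference into a between-participant variance:
    ``"mean"`` (N/k, the default) or ``"anova_n0"`` (the unbalanced-design
    ANOVA constant ``(N - sum(ni^2)/N) / (k - 1)``).
    """
    groups = list(ds.data.values())
    k = len(groups)
    ni = np.array([len(g) for g in groups], dtype=float)
    N = float(ni.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ni * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    ms_p = ss_between / (k - 1)
    ms_r = ss_within / (N - k)
    if nbar_mode == "mean":
        nbar = N / k
    elif nbar_mode == "anova_n0":
        nbar = (N - float(np.sum(ni**2)) / N) / (k - 1)
    else:
        raise ParameterError(f"unknown nbar_mode {nbar_mode!r}")
    var_between = max(0.0, (ms_p - ms_r) / nbar)
    var_total = var_between + ms_r
    return {
        "ms_participant": ms_p,
        "ms_residual": ms_r,
        "var_between": var_between,
        "var_total": var_total,
        "sd": float(np.sqrt(var_total)),
        "n_bar": nbar,
        "ss_between": ss_between,
        "ss_within": ss_within,
    }


def bland_altman(ds: DifferenceSet, nbar_mode: str = "mean") -> AgreementResult:
    """Repeated-measures Bland-Altman summary of one difference set.

    Bias is the grand mean of the pooled differences; the limits of agreement
    are ``bias +/- 1.96 SD`` with SD from the variance partition; RMSE is the
    square root of the residual mean square.
    """
    vp = variance_partition(ds, nbar_mode=nbar_mode)
    bias = float(ds.pooled().mean())
    sd = vp["sd"]
    return AgreementResult(
        bias=bias,
        ms_participant=vp["ms_participant"],
        ms_residual=vp["ms_residual"],
        var_between=vp["var_between"],
        var_total=vp["var_total"],
        sd=sd,
        loa_lower=bias - LOA_FACTOR * sd,
        loa_upper=bias + LOA_FACTOR * sd,
        rmse=float(np.sqrt(vp["ms_residual"])),
        n_participants=ds.n_participants,
        n_obs=ds.n_obs,
        labels=dict(ds.labels),
    )


def anova_oneway(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Standard one-way ANOVA with partial eta-squared and Cohen's f."""
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 2 for a in arrs):
        raise ParameterError("each group needs at least 2 values")
    ni = np.array([len(a) for a in arrs], dtype=float)
    N = float(ni.sum())
    k = len(arrs)
    grand = float(np.concatenate(arrs).mean())
    means = np.array([a.mean() for a in arrs])
    ss_b = float(np.sum(ni * (means - grand) ** 2))
    ss_w = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrs, means)))
    df_g = k - 1
    df_e = int(N) - k
    if df_e <= 0:
        raise ParameterError("not enough observations for the error term")
    ms_b = ss_b / df_g
    ms_w = ss_w / df_e
    if ms_w == 0.0:
        f_stat = 0.0 if ms_b == 0.0 else np.inf
    else:
        f_stat = ms_b / ms_w
    p = float(sstats.f.sf(f_stat, df_g, df_e)) if np.isfinite(f_stat) else 0.0
    denom = ss_b + ss_w
    eta2p = ss_b / denom if denom > 0 else 0.0
    cohens_f = float(np.sqrt(eta2p / (1.0 - eta2p))) if eta2p < 1.0 else np.inf
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=p,
        partial_eta_squared=float(eta2p),
        cohens_f=cohens_f,
        df_group=df_g,
        df_error=df_e,
        alpha=alpha,
    )


def _rmse_groups(results: list[AgreementResult], factor: str, fixed: dict) -> dict:
    groups: dict[str, list[float]] = {}
    for res in results:
        if any(res.labels.get(k) != v for k, v in fixed.items()):
            continue
        groups.setdefault(str(res.labels[factor]), []).append(res.rmse)
    return {k: np.asarray(v) for k, v in groups.items()}


def compare_methods(
    results: list[AgreementResult], plane: str, expected_per_group: int | None = 40
) -> AnovaResult:
    """One-way ANOVA: does mean RMSE differ between methods within a plane?"""
    groups = _rmse_groups(results, factor="method", fixed={"placement": plane})
    _check_counts(groups, expected_per_group)
    return anova_oneway(groups)


def compare_planes(
    results: list[AgreementResult], method: str, expected_per_group: int | None = 40
) -> AnovaResult:
    """One-way ANOVA: does mean RMSE differ between camera placements within a
    method?"""
    groups = _rmse_groups(results, factor="placement", fixed={"method": method})
    _check_counts(groups, expected_per_group)
    return anova_oneway(groups)


def _check_counts(groups: dict, expected: int | None) -> None:
    if len(groups) < 2:
        raise ParameterError("comparison needs two groups")
    sizes = {k: len(v) for k, v in groups.items()}
    if len(set(sizes.values())) != 1:
        raise ParameterError(f"mismatched difference-set counts: {sizes}")
    if expected is not None and set(sizes.values()) != {expected}:
        raise ParameterError(f"expected {expected} RMSE values per group, got {sizes}")


def simulate_difference_set(
    bias: float,
    sd_between: float,
    sd_within: float,
    n_participants: int,
    n_obs: int,
    rng: np.random.Generator,
    standardize: bool = True,
    labels: dict | None = None,
) -> DifferenceSet:
    """Gaussian difference data with known bias and variance components.

    With ``standardize=True`` the participant effects and residuals are
    rescaled to their exact target sample moments, so estimator checks are not
    confounded by sampling variability of the draw itself.
    """
    b = rng.normal(0.0, 1.0, size=n_participants)
    if standardize:
        b = (b - b.mean()) / b.std(ddof=1)
    effects = sd_between * b
    data = {}
    resid_all = rng.normal(0.0, 1.0, size=(n_participants, n_obs))
    if standardize:
        resid_all = resid_all - resid_all.mean(axis=1, keepdims=True)
        pooled_ms = np.sum(resid_all**2) / (n_participants * (n_obs - 1))
        resid_all = resid_all / np.sqrt(pooled_ms)
    for i in range(n_participants):
        data[f"P{i + 1:02d}"] = bias + effects[i] + sd_within * resid_all[i]
    return DifferenceSet(labels=dict(labels or {}), data=data)
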