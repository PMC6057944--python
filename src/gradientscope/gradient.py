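"""Polyserial gradient statistics and dual-criterion biomarker selection.

The central statistic: each CLR-transformed feature is correlated with the
ordered lifestyle factor (captive < semi-captive < semi-wild < wild) via the
polyserial correlation — the ML estimate of the correlation between the
observed continuous variable and the standard-normal latent variable assumed
to underlie the ordinal one.  Estimation is the common two-step scheme:

1. thresholds tau_j = Phi^-1(cumulative category proportions) from the
   ordinal marginals;
2. rho maximises the conditional log-likelihood
   sum_i log[ Phi((tau_{y_i} - rho z_i)/sqrt(1-rho^2))
            - Phi((tau_{y_i - 1} - rho z_i)/sqrt(1-rho^2)) ]
   over rho in (-0.999, 0.999), with z the standardised observed variable.

Two p-values accompany each estimate: a likelihood-ratio chi-square
(2(l(rho_hat) - l(0)), df=1) and a Wald p from rho_hat and its numerical
observed-information standard error ("rho confidence p").  A feature is
selected as a gradient biomarker only if it clears all of: |rho| >= 0.3,
family-adjusted chi-square p <= 0.05, raw Wald p <= 0.05, and a
family-adjusted Wilcoxon rank-sum p <= 0.05 comparing the gradient extrema
(the combined captive + semi-captive group against the wild group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .compositional import CLRMatrix
from .core_data import SampleMetadata
from .diversity import wilcoxon_rank_sum

__all__ = [
    "PolyserialFit",
    "polyserial",
    "holm_adjust",
    "bh_adjust",
    "extrema_grouping",
    "SelectionThresholds",
    "apply_selection",
    "gradient_scan",
]

_RHO_BOUND = 0.999

EXTREMA_CAPTIVE_SIDE = "(Semi-)captive"
EXTREMA_WILD_SIDE = "wild"


@dataclass
class PolyserialFit:
    """Two-step ML polyserial fit of a continuous x against ordinal y."""

    rho: float
    se_rho: float
    thresholds: np.ndarray  # k-1 latent cutpoints, strictly increasing
    loglik: float
    chi2: float       # LRT statistic 2(l(rho) - l(0))
    p_chi2: float     # chi-square p, df = 1
    p_wald: float     # two-sided normal p for rho/se ("rho confidence p")
    n: int


def _ordinal_thresholds(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Category codes (0-based, dense) and Phi^-1 cumulative-proportion cuts."""
    levels = np.unique(y)
    codes = np.searchsorted(levels, y)
    props = np.bincount(codes) / y.size
    tau = sps.norm.ppf(np.cumsum(props)[:-1])
    return codes, tau


def _polyserial_loglik(rho: float, z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> float:
    s = np.sqrt(1.0 - rho * rho)
    upper = sps.norm.cdf((hi - rho * z) / s)
    lower = sps.norm.cdf((lo - rho * z) / s)
    return float(np.log(np.clip(upper - lower, 1e-300, None)).sum())


def polyserial(x, y) -> PolyserialFit:
    """Polyserial correlation between continuous ``x`` and ordinal ``y``.

    ``y`` may be integer level codes or orderable labels; at least two
    distinct levels must be present and ``x`` must vary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.unique(y).size < 2:
        raise ValueError("single ordinal level: polyserial correlation undefined")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("x is constant: polyserial correlation undefined")
    z = (x - x.mean()) / sd
    codes, tau = _ordinal_thresholds(y)
    bounds = np.concatenate([[-np.inf], tau, [np.inf]])
    lo, hi = bounds[codes], bounds[codes + 1]

    res = minimize_scalar(
        lambda r: -_polyserial_loglik(r, z, lo, hi),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    loglik = -float(res.fun)

    # observed information by central second difference
    h = 1e-4
    r_plus = min(rho + h, _RHO_BOUND)
    r_minus = max(rho - h, -_RHO_BOUND)
    ll_p = _polyserial_loglik(r_plus, z, lo, hi)
    ll_m = _polyserial_loglik(r_minus, z, lo, hi)
    curvature = (ll_p - 2 * loglik + ll_m) / ((r_plus - rho) * (rho - r_minus))
    se = float(np.sqrt(-1.0 / curvature)) if curvature < 0 else np.inf

    chi2 = max(0.0, 2.0 * (loglik - _polyserial_loglik(0.0, z, lo, hi)))
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    p_wald = float(2.0 * sps.norm.sf(abs(rho) / se)) if np.isfinite(se) else 1.0
    return PolyserialFit(
        rho=rho, se_rho=se, thresholds=tau, loglik=loglik,
        chi2=chi2, p_chi2=p_chi2, p_wald=p_wald, n=x.size,
    )


def _validated_pvalues(pvalues) -> np.ndarray:
    arr = np.asarray(pvalues, dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down family-wise error rate adjustment."""
    arr = _validated_pvalues(pvalues)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up false-discovery-rate adjustment."""
    arr = _validated_pvalues(pvalues)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def extrema_grouping(metadata: SampleMetadata) -> pd.Series:
    """Binary labels for the gradient-extrema comparison.

    Captive and semi-captive samples are pooled into a single
    "(Semi-)captive" group (accumulating enough samples to power the pairwise
    test); wild samples form the other group; semi-wild samples are excluded
    (NaN) from the comparison.
    """
    lifestyles = metadata.lifestyle()
    present = set(lifestyles)
    if "wild" not in present:
        raise ValueError("extrema comparison requires a wild group")
    if not ({"captive", "semi-captive"} & present):
        raise ValueError("extrema comparison requires a captive-side group")
    mapping = {
        "captive": EXTREMA_CAPTIVE_SIDE,
        "semi-captive": EXTREMA_CAPTIVE_SIDE,
        "semi-wild": np.nan,
        "wild": EXTREMA_WILD_SIDE,
    }
    return lifestyles.map(mapping)


@dataclass
class SelectionThresholds:
    """Dual-criterion significance rule for gradient biomarkers."""

    min_abs_rho: float = 0.3
    max_adj_p: float = 0.05       # on the family-adjusted chi-square p
    max_confidence_p: float = 0.05  # on the raw Wald p
    max_extrema_p: float = 0.05   # on the family-adjusted Wilcoxon p
    display_tier_taxa: float = 0.6
    display_tier_pathway: float = 0.75


def apply_selection(
    results: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
    mode: str = "taxa",
) -> pd.DataFrame:
    """Set the ``selected`` and ``display_tier`` flags on a scan frame.

    Requires columns rho, rho_p_adj, rho_confidence_p, wilcoxon_p_adj.
    An association failing any single criterion is considered insignificant.
    """
    tier = (
        thresholds.display_tier_pathway if mode == "pathway"
        else thresholds.display_tier_taxa
    )
    out = results.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        out["selected"] = (
            (out["rho"].abs() >= thresholds.min_abs_rho)
            & (out["rho_p_adj"] <= thresholds.max_adj_p)
            & (out["rho_confidence_p"] <= thresholds.max_confidence_p)
            & (out["wilcoxon_p_adj"] <= thresholds.max_extrema_p)
        ).fillna(False)
        out["display_tier"] = out["selected"] & (out["rho"].abs() > tier)
    return out


def gradient_scan(
    clr: CLRMatrix,
    metadata: SampleMetadata,
    mode: str = "taxa",
    thresholds: SelectionThresholds = SelectionThresholds(),
    adjust: str = "holm",
) -> pd.DataFrame:
    """Scan every CLR feature for association with the lifestyle gradient.

    Per feature: polyserial correlation against the 1..4 lifestyle coding
    (wildness-ascending) plus a Wilcoxon rank-sum test on the gradient
    extrema.  The chi-square p-values are adjusted across features as one
    family, the Wilcoxon p-values as another (``adjust`` = "holm" for the
    primary pass, "bh" for the replicate-collapse validation pass).  Returns
    a frame indexed by feature with columns rho, se_rho, rho_p, rho_p_adj,
    rho_confidence_p, wilcoxon_p, wilcoxon_p_adj, selected, display_tier,
    note.
    """
    if adjust not in ("holm", "bh"):
        raise ValueError("adjust must be 'holm' or 'bh'")
    meta = metadata.data.loc[clr.sample_ids]
    levels = SampleMetadata(meta).levels().to_numpy()
    extrema = extrema_grouping(SampleMetadata(meta))
    cap_mask = (extrema == EXTREMA_CAPTIVE_SIDE).to_numpy()
    wild_mask = (extrema == EXTREMA_WILD_SIDE).to_numpy()

    level_counts = pd.Series(levels).value_counts()
    note_small = "" if level_counts.min() >= 4 else "level with < 4 samples"

    rows = []
    for fid in clr.feature_ids:
        x = clr.data.loc[fid].to_numpy()
        note = note_small
        try:
            fit = polyserial(x, levels)
            rho, se, p_chi2, p_wald = fit.rho, fit.se_rho, fit.p_chi2, fit.p_wald
        except ValueError as exc:
            rho = se = np.nan
            p_chi2 = p_wald = np.nan
            note = (note + "; " if note else "") + str(exc)
        if cap_mask.any() and wild_mask.any():
            _, p_wx = wilcoxon_rank_sum(x[cap_mask], x[wild_mask])
        else:  # pragma: no cover - guarded by extrema_grouping
            p_wx = np.nan
        rows.append((fid, rho, se, p_chi2, p_wald, p_wx, note))

    df = pd.DataFrame(
        rows,
        columns=["feature_id", "rho", "se_rho", "rho_p",
                 "rho_confidence_p", "wilcoxon_p", "note"],
    ).set_index("feature_id")

    adjuster = holm_adjust if adjust == "holm" else bh_adjust
    for raw, adj in (("rho_p", "rho_p_adj"), ("wilcoxon_p", "wilcoxon_p_adj")):
        ok = df[raw].notna()
        df[adj] = np.nan
        if ok.any():
            df.loc[ok, adj] = adjuster(df.loc[ok, raw].to_numpy())
    return apply_selection(df, thresholds, mode=mode)
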