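"""Region-wise summaries, t-tests, inequality bookkeeping, histograms.

The headline quantity is the average normalized WCN of each surface
subregion — ⟨z⟩_C, ⟨z⟩_P, ⟨z⟩_N per subunit, ⟨zWCN⟩_C/P/N per dataset —
and the ordering ⟨zWCN⟩_C > ⟨zWCN⟩_N > ⟨zWCN⟩_P that marks interface
cores as rigid and rims as flexible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .interface import RegionLabel
from .structure_io import Subunit
from .wcn import compute_wcn


@dataclass
class RegionStats:
    """Per-subunit region means of normalized WCN and residue counts."""

    subunit_id: str
    mean_c: float | None
    mean_p: float | None
    mean_n: float | None
    n_c: int
    n_p: int
    n_n: int


@dataclass
class TestResult:
    """Two-sample Student's t-test (pooled variance)."""

    t: float
    df: int
    p: float


@dataclass
class DatasetSummary:
    """Dataset-level twin of the per-region summary table."""

    name: str
    zwcn_mean: dict[str, float]          # ⟨zWCN⟩ per region over pooled residues
    subunit_mean: dict[str, float]       # mean over subunits of per-subunit ⟨z⟩
    t_tests: dict[str, TestResult]       # c_vs_n, p_vs_n, c_vs_p on zWCN pools
    inequalities: dict[str, tuple[int, int, float]]  # (num, den, percent)
    n_subunits: int
    n_subunits_analyzed: int
    n_residues: dict[str, int] = field(default_factory=dict)


def region_means(z: np.ndarray, labels: list[RegionLabel], subunit_id: str = "") -> RegionStats:
    """Arithmetic mean of z per region; empty regions yield missing means."""
    z = np.asarray(z, dtype=float)

    def _mean(region: RegionLabel) -> tuple[float | None, int]:
        vals = z[[lab == region for lab in labels]]
        vals = vals[np.isfinite(vals)]
        return (float(vals.mean()) if len(vals) else None), len(vals)

    mc, nc = _mean(RegionLabel.CENTRAL)
    mp, np_ = _mean(RegionLabel.PERIPHERAL)
    mn, nn = _mean(RegionLabel.NON_INTERFACE)
    return RegionStats(subunit_id, mc, mp, mn, nc, np_, nn)


def students_t(group_a, group_b) -> TestResult:
    """Classical pooled-variance two-sample t-test, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(t=float(res.statistic), df=len(a) + len(b) - 2, p=float(res.pvalue))


def welch_t(group_a, group_b) -> TestResult:
    """Welch variant (unequal variances); not used by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(t=float(res.statistic), df=int(res.df), p=float(res.pvalue))


def inequality_fractions(
    stats_list: list[RegionStats],
) -> dict[str, tuple[int, int, float]]:
    """Count subunits obeying each strict region-mean inequality.

    Returns ``{comparison: (numerator, denominator, percent)}`` for
    ⟨z⟩_C > ⟨z⟩_P, ⟨z⟩_P < ⟨z⟩_N and ⟨z⟩_C > ⟨z⟩_N. A subunit enters a
    comparison's denominator only when both means are defined; ties count
    as not satisfying.
    """
    comparisons = {
        "c_gt_p": lambda s: (s.mean_c, s.mean_p, lambda x, y: x > y),
        "p_lt_n": lambda s: (s.mean_p, s.mean_n, lambda x, y: x < y),
        "c_gt_n": lambda s: (s.mean_c, s.mean_n, lambda x, y: x > y),
    }
    out = {}
    for key, getter in comparisons.items():
        num = den = 0
        for s in stats_list:
            x, y, op = getter(s)
            if x is None or y is None:
                continue
            den += 1
            if op(x, y):
                num += 1
        if den == 0:
            raise ValueError(f"no subunit eligible for comparison {key}")
        out[key] = (num, den, round(100.0 * num / den, 1))
    return out


def zwcn_histograms(
    zwcn: np.ndarray,
    labels: list[RegionLabel],
    bin_width: float = 0.25,
    regions: tuple[RegionLabel, ...] = (
        RegionLabel.CENTRAL,
        RegionLabel.PERIPHERAL,
        RegionLabel.NON_INTERFACE,
    ),
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Relative-frequency histograms per region over one shared binning.

    Bin edges align to multiples of ``bin_width`` spanning all requested
    regions' values; each region's frequencies sum to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    zwcn = np.asarray(zwcn, dtype=float)
    values = {}
    for region in regions:
        vals = zwcn[[lab == region for lab in labels]]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"no residues in requested region {region}")
        values[region.value] = vals
    allv = np.concatenate(list(values.values()))
    lo = math.floor(allv.min() / bin_width) * bin_width
    hi = math.ceil(allv.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    freqs = {}
    for name, vals in values.items():
        counts, _ = np.histogram(vals, bins=edges)
        freqs[name] = counts / counts.sum()
    return edges, freqs


def wcn_bfactor_profile(
    subunit: Subunit,
    w: np.ndarray | None = None,
    representative: str = "CA",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Compare experimental B-factors with the reciprocal-WCN profile.

    Per residue, the B-factor (Cα atom, mean of heavy atoms as fallback)
    and 1/WCN are each z-normalized over the same residue set; returns
    (z_bfactor, z_inv_wcn, Pearson r). High r means packing density alone
    recovers the thermal-fluctuation profile.
    """
    if w is None:
        w = compute_wcn(subunit, representative=representative)
    w = np.asarray(w, dtype=float)
    b = []
    for res in subunit.residues:
        ca = res.get_atom("CA")
        b.append(ca.bfactor if ca is not None else float(np.mean([a.bfactor for a in res.atoms])))
    b = np.asarray(b, dtype=float)
    if np.ptp(b) == 0.0:
        raise ValueError("B-factors constant or missing: no profile to compare")
    inv_w = 1.0 / w
    zb = (b - b.mean()) / b.std()
    zw = (inv_w - inv_w.mean()) / inv_w.std()
    r = float(np.corrcoef(zb, zw)[0, 1])
    return zb, zw, r
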