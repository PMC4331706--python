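"""Per-complex analysis and dataset-level aggregation.

``analyze_complex`` runs the full per-subunit chain — unbound/bound
accessible areas, surface mask, weighted contact number, per-subunit
z-scores, interface detection and core/rim partition — and returns one
residue-level profile plus region means per subunit. ``run_dataset``
iterates a manifest, drops subunits with too few central residues (the
t-tests need populated groups), pools the retained surface residues for
the global zWCN normalization, and emits the dataset summary tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interface as iface
from . import sasa as sasa_mod
from . import stats as stats_mod
from . import wcn as wcn_mod
from .structure_io import (
    ComplexStructure,
    ManifestEntry,
    extract_subunit,
    load_manifest,
    parse_pdb,
)

log = logging.getLogger(__name__)

REGION_KEYS = {"c": iface.RegionLabel.CENTRAL, "p": iface.RegionLabel.PERIPHERAL, "n": iface.RegionLabel.NON_INTERFACE}


@dataclass
class RunConfig:
    """Knobs of the analysis; defaults are the reference thresholds.

    contact_cutoff: heavy-atom distance (Å, inclusive) defining interface
    membership. central_rsasa: bound-state relative accessibility at or
    below which an interface residue counts as central. min_central:
    subunits with fewer central residues are excluded from dataset-level
    statistics (region comparisons need populated groups).
    """

    manifest: Path | None = None
    pdb_dir: Path | None = None
    out_dir: Path | None = None
    contact_cutoff: float = 5.0
    central_rsasa: float = 0.05
    probe: float = 1.4
    n_points: int = 960
    min_central: int = 2
    max_asa_table: str = "rost_sander"
    representative: str = "CA"
    bin_width: float = 0.25
    dataset_name: str = "dataset"

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.central_rsasa <= 0 or self.probe <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_central < 0:
            raise ValueError("min_central must be >= 0")


@dataclass
class SubunitResult:
    """Everything computed for one unbound subunit of one complex."""

    subunit_id: str
    pdb_id: str
    group: frozenset[str]
    category: str
    profile: pd.DataFrame | None = None
    region_stats: stats_mod.RegionStats | None = None
    skip_reason: str | None = None
    w: np.ndarray | None = None
    z: np.ndarray | None = None
    surface_mask: np.ndarray | None = None
    labels: list | None = None
    zwcn: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return self.skip_reason is None


def analyze_complex(
    structure: ComplexStructure, entry: ManifestEntry, cfg: RunConfig | None = None
) -> list[SubunitResult]:
    """Analyze every subunit of one complex as an unbound unit.

    Subunits that cannot be analyzed (fewer than two surface residues,
    degenerate WCN variance) are returned with a ``skip_reason`` instead
    of aborting the complex.
    """
    cfg = cfg or RunConfig()
    max_asa = sasa_mod.MAX_ASA_TABLES[cfg.max_asa_table]
    groups = entry.subunit_chain_groups
    sasa_pairs = sasa_mod.bound_and_unbound_sasa(
        structure, groups, probe=cfg.probe, n_points=cfg.n_points
    )
    results = []
    for group, (unbound, bound) in zip(groups, sasa_pairs):
        gid = ":".join(sorted(group))
        sid = f"{structure.pdb_id}/{gid}"
        result = SubunitResult(
            subunit_id=sid, pdb_id=structure.pdb_id, group=group, category=entry.category
        )
        results.append(result)
        subunit = extract_subunit(structure, group)
        surface = iface.surface_residues(unbound)
        if surface.sum() < 2:
            result.skip_reason = f"only {int(surface.sum())} surface residues"
            continue
        try:
            w = wcn_mod.compute_wcn(subunit, representative=cfg.representative)
            z = wcn_mod.zscore_per_subunit(w, surface)
        except ValueError as exc:
            result.skip_reason = str(exc)
            continue
        partner_chains = {c for g in groups if g is not group for c in g}
        partner_coords = np.vstack(
            [
                r.coords()
                for cid in structure.chains
                if cid in partner_chains
                for r in structure.chains[cid]
            ]
        )
        contact = iface.interface_residues(
            subunit, partner_coords, surface, cutoff=cfg.contact_cutoff
        )
        bound_rsasa = np.array(
            [
                sasa_mod.relative_sasa(area, res.res_name, max_asa)
                for area, res in zip(bound, subunit.residues)
            ]
        )
        labels = iface.partition_interface(
            surface, contact, bound_rsasa, threshold=cfg.central_rsasa
        )
        result.profile = pd.DataFrame(
            {
                "chain": [r.chain_id for r in subunit.residues],
                "seq_id": [r.seq_id for r in subunit.residues],
                "res_name": [r.res_name for r in subunit.residues],
                "wcn": w,
                "sasa_unbound": unbound,
                "sasa_bound": bound,
                "rsasa_bound": bound_rsasa,
                "region": [str(lab) for lab in labels],
                "z": z,
                "zwcn": np.nan,
            }
        )
        result.region_stats = stats_mod.region_means(z, labels, subunit_id=sid)
        result.w = w
        result.z = z
        result.surface_mask = surface
        result.labels = labels
    return results


def run_dataset(cfg: RunConfig) -> stats_mod.DatasetSummary:
    """Analyze a whole manifest and aggregate the dataset summary.

    Missing structure files are logged and skipped. Subunits with fewer
    than ``cfg.min_central`` central residues are excluded from every
    dataset-level statistic. Outputs (summary.json, table1.tsv,
    per_subunit.tsv, histograms.tsv, per_residue/*.tsv) are written when
    ``cfg.out_dir`` is set.
    """
    if cfg.manifest is None or cfg.pdb_dir is None:
        raise ValueError("run_dataset needs cfg.manifest and cfg.pdb_dir")
    entries = load_manifest(Path(cfg.manifest).read_text())
    if not entries:
        raise ValueError("empty manifest")

    all_results: list[SubunitResult] = []
    n_missing = 0
    for entry in entries:
        path = Path(cfg.pdb_dir) / f"{entry.pdb_id}.pdb"
        if not path.exists():
            log.warning("structure file missing, skipped: %s", path)
            n_missing += 1
            continue
        structure = parse_pdb(path.read_text(), pdb_id=entry.pdb_id)
        all_results.extend(analyze_complex(structure, entry, cfg))
    if n_missing:
        log.warning("%d manifest entries had no structure file", n_missing)

    analyzed = [r for r in all_results if r.ok]
    retained = [r for r in analyzed if r.region_stats.n_c >= cfg.min_central]
    filtered = [r for r in analyzed if r.region_stats.n_c < cfg.min_central]
    if not retained:
        raise ValueError("no subunit survived analysis and the min_central filter")

    zwcn_list = wcn_mod.zscore_global(
        [r.w for r in retained], [r.surface_mask for r in retained]
    )
    for r, zw in zip(retained, zwcn_list):
        r.zwcn = zw
        r.profile["zwcn"] = zw

    pooled_zwcn = np.concatenate([r.zwcn for r in retained])
    pooled_labels = [lab for r in retained for lab in r.labels]
    pools = {
        key: pooled_zwcn[[lab == region for lab in pooled_labels]]
        for key, region in REGION_KEYS.items()
    }
    pools = {k: v[np.isfinite(v)] for k, v in pools.items()}

    zwcn_mean = {k: float(v.mean()) for k, v in pools.items()}
    t_tests = {
        "c_vs_n": stats_mod.students_t(pools["c"], pools["n"]),
        "p_vs_n": stats_mod.students_t(pools["p"], pools["n"]),
        "c_vs_p": stats_mod.students_t(pools["c"], pools["p"]),
    }
    region_stats = [r.region_stats for r in retained]
    subunit_mean = {}
    for key in REGION_KEYS:
        vals = [getattr(s, f"mean_{key}") for s in region_stats]
        vals = [v for v in vals if v is not None]
        subunit_mean[key] = float(np.mean(vals)) if vals else float("nan")
    inequalities = stats_mod.inequality_fractions(region_stats)

    summary = stats_mod.DatasetSummary(
        name=cfg.dataset_name,
        zwcn_mean=zwcn_mean,
        subunit_mean=subunit_mean,
        t_tests=t_tests,
        inequalities=inequalities,
        n_subunits=len(all_results),
        n_subunits_analyzed=len(retained),
        n_residues={k: int(len(v)) for k, v in pools.items()},
    )

    if cfg.out_dir is not None:
        _write_outputs(cfg, summary, retained, filtered,
                       [r for r in all_results if not r.ok], pooled_zwcn, pooled_labels)
    return summary


def _fmt(x: float | None) -> str:
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.6g}"


def _write_outputs(cfg, summary, retained, filtered, skipped, pooled_zwcn, pooled_labels):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload = {
        "dataset": summary.name,
        "zwcn_mean": summary.zwcn_mean,
        "subunit_mean": summary.subunit_mean,
        "t_tests": {
            k: {"t": v.t, "df": v.df, "p": v.p} for k, v in summary.t_tests.items()
        },
        "inequalities": {
            k: {"num": v[0], "den": v[1], "percent": v[2]}
            for k, v in summary.inequalities.items()
        },
        "n_subunits": summary.n_subunits,
        "n_subunits_analyzed": summary.n_subunits_analyzed,
        "n_residues": summary.n_residues,
        "excluded_min_central": sorted(r.subunit_id for r in filtered),
        "skipped": sorted(f"{r.subunit_id}: {r.skip_reason}" for r in skipped),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    header = "dataset\t⟨zWCN⟩_N\t⟨zWCN⟩_C\t⟨zWCN⟩_P\t⟨⟨z⟩_N⟩\t⟨⟨z⟩_C⟩\t⟨⟨z⟩_P⟩"
    row = "\t".join(
        [summary.name]
        + [_fmt(summary.zwcn_mean[k]) for k in ("n", "c", "p")]
        + [_fmt(summary.subunit_mean[k]) for k in ("n", "c", "p")]
    )
    (out / "table1.tsv").write_text(header + "\n" + row + "\n")

    lines = ["pdb\tsubunit\tn_C\tn_P\tn_N\t⟨z⟩_C\t⟨z⟩_P\t⟨z⟩_N"]
    for r in retained:
        s = r.region_stats
        lines.append(
            "\t".join(
                [r.pdb_id, ":".join(sorted(r.group)), str(s.n_c), str(s.n_p), str(s.n_n),
                 _fmt(s.mean_c), _fmt(s.mean_p), _fmt(s.mean_n)]
            )
        )
    (out / "per_subunit.tsv").write_text("\n".join(lines) + "\n")

    edges, freqs = stats_mod.zwcn_histograms(
        pooled_zwcn, pooled_labels, bin_width=cfg.bin_width
    )
    lines = ["bin_lo\tbin_hi\tcentral\tperipheral\tnon_interface"]
    for i in range(len(edges) - 1):
        lines.append(
            f"{edges[i]:.4f}\t{edges[i + 1]:.4f}\t"
            f"{freqs['central'][i]:.6g}\t{freqs['peripheral'][i]:.6g}\t"
            f"{freqs['non_interface'][i]:.6g}"
        )
    (out / "histograms.tsv").write_text("\n".join(lines) + "\n")

    res_dir = out / "per_residue"
    res_dir.mkdir(exist_ok=True)
    for r in retained:
        name = f"{r.pdb_id}_{'-'.join(sorted(r.group))}.tsv"
        r.profile.to_csv(res_dir / name, sep="\t", index=False, float_format="%.6g")
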