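"""End-to-end genome scan orchestration.

``run_scan`` goes from study inputs to results: phenotype scoring (EL/FEL)
→ affected selection → affected-pair enumeration → marker QC → per-marker
APM scores with a gene-dropping null → per-chromosome linked nulls for
multipoint windows and a 1-cM interpolation grid → genome-wide
(experiment-wise) adjustment over all loci.  One linked gene-drop ensemble
per chromosome, seeded hierarchically, serves every locus on it, so
per-replicate genome-wide Z curves are well defined.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .genedrop import AlleleFrequencyTable, GeneticMap, drop_linked_batch, haldane_theta
from .linkage import (
    PairScorer,
    SharingWeight,
    genomewide_adjust,
    grid_multipoint,
    multipoint_window,
    z_and_pvalues,
)
from .pedigree import Pedigree, enumerate_affected_pairs
from .phenotype import (
    ExpectedLifespanTable,
    SelectionRule,
    compute_phenotypes,
    quartile_thresholds,
    select_affected,
)

__all__ = [
    "ScanConfig",
    "StudyInputs",
    "ScanResults",
    "ScanAbort",
    "read_study_inputs",
    "run_scan",
    "summarize_regions",
    "write_report",
]


class ScanAbort(RuntimeError):
    """The scan cannot proceed (e.g. no affected pairs)."""


@dataclass(frozen=True)
class ScanConfig:
    """Run configuration (YAML-loadable)."""

    n_reps: int = 500
    seed: int = 0
    weight_form: str = "inverse_sqrt"
    window_cm: float = 10.0
    grid_step_cm: float = 1.0
    call_rate_threshold: float = 0.50
    min_kinship: Optional[float] = None  # None: any phi > 0
    selection_mode: str = "el_fel_thresholds"  # or el_fel_quartile / attained_age
    el_min: float = 3.0
    fel_min: float = 1.75
    age_min: float = 100.0
    region_p_threshold: float = 0.01
    empirical_convention: str = "plugin"

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def selection_rule(self, phen: pd.DataFrame) -> SelectionRule:
        if self.selection_mode == "el_fel_thresholds":
            return SelectionRule("el_fel_thresholds", el_min=self.el_min,
                                 fel_min=self.fel_min)
        if self.selection_mode == "el_fel_quartile":
            return SelectionRule(
                "el_fel_thresholds",
                el_min=quartile_thresholds(phen["EL"].dropna()),
                fel_min=quartile_thresholds(phen["FEL"].dropna()),
            )
        if self.selection_mode == "attained_age":
            return SelectionRule("attained_age", age_min=self.age_min)
        raise ValueError(f"unknown selection mode {self.selection_mode!r}")


@dataclass
class StudyInputs:
    """Cross-validated inputs for one scan run."""

    ped: Pedigree
    panel: sio.GenotypePanel
    gmap: GeneticMap
    freqs: AlleleFrequencyTable
    phenotypes: pd.DataFrame  # id-indexed: sex, birth_year, death_year, attained_age
    el_table: ExpectedLifespanTable
    config: ScanConfig = field(default_factory=ScanConfig)


@dataclass
class ScanResults:
    """Scan outputs: per-marker singlepoint rows, per-marker multipoint
    window rows, 1-cM grid rows, region summaries, QC, and run metadata."""

    singlepoint: pd.DataFrame
    multipoint: pd.DataFrame
    grid: pd.DataFrame
    regions: pd.DataFrame
    qc: pd.DataFrame
    n_affected: int
    n_pairs: int
    degenerate_markers: list[str]
    metadata: dict


def read_study_inputs(
    ped_path,
    map_path,
    phen_path,
    expected_path,
    freq_path=None,
    control_ids: Optional[list[str]] = None,
    config: Optional[ScanConfig] = None,
) -> StudyInputs:
    """Read and cross-validate all study files.

    Allele frequencies come from ``freq_path`` if given, otherwise they are
    estimated by counting over ``control_ids``.  Raises informative errors
    on id mismatches, marker/map mismatches, and alleles absent from the
    frequency table.
    """
    config = config or ScanConfig()
    gmap = sio.read_map(map_path)
    ped, panel = sio.read_ped(ped_path, gmap)
    phen = sio.read_phenotypes(phen_path)
    el_table = sio.read_expected_lifespans(expected_path)
    unknown_ids = set(phen.index) - set(ped.ids)
    if unknown_ids:
        raise ValueError(
            f"phenotype table ids not in pedigree: {sorted(unknown_ids)[:5]}"
        )
    if freq_path is not None:
        freqs = sio.read_frequencies(freq_path)
    elif control_ids:
        freqs = sio.estimate_allele_frequencies(panel, control_ids)
    else:
        raise ValueError("provide a frequency table or control ids to estimate one")
    for m in panel.markers:
        if m not in freqs:
            continue  # dropped later by QC if untyped; scored only if covered
        col = panel.geno[:, panel._midx[m], :]
        observed = np.unique(col[col != 0])
        known = set(int(a) for a in freqs.alleles(m))
        bad = [int(a) for a in observed if int(a) not in known]
        if bad:
            raise ValueError(
                f"marker {m!r}: allele(s) {bad} observed in genotypes but absent "
                "from the frequency table"
            )
    # attach lifespans/birth years to pedigree members
    members = []
    for ind in ped.members:
        if ind.id in phen.index:
            row = phen.loc[ind.id]
            members.append(
                dataclasses.replace(
                    ind,
                    birth_year=None if pd.isna(row["birth_year"]) else int(row["birth_year"]),
                    death_year=None if pd.isna(row["death_year"]) else int(row["death_year"]),
                    attained_age=None if pd.isna(row["attained_age"]) else float(row["attained_age"]),
                )
            )
        else:
            members.append(ind)
    ped = Pedigree(members)
    return StudyInputs(ped, panel, gmap, freqs, phen, el_table, config)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def run_scan(inputs: StudyInputs) -> ScanResults:
    """Run the full linkage scan (deterministic under the configured seed)."""
    cfg = inputs.config
    weight = SharingWeight(cfg.weight_form)
    qc, panel = sio.filter_markers(inputs.panel, cfg.call_rate_threshold)
    # drop markers without frequency coverage (e.g. monomorphic in controls)
    panel = panel.subset_markers([m for m in panel.markers if m in inputs.freqs])

    phen = compute_phenotypes(inputs.ped, inputs.el_table)
    phen["attained_age"] = inputs.phenotypes["attained_age"]
    rule = cfg.selection_rule(phen)
    affected = select_affected(phen, rule)
    affected &= set(panel.ids)
    pairs = enumerate_affected_pairs(inputs.ped, affected, cfg.min_kinship)
    if not pairs:
        raise ScanAbort(
            f"no affected relative pairs ({len(affected)} affected individuals); "
            "cannot run a linkage scan"
        )

    idx = {iid: k for k, iid in enumerate(inputs.ped.ids)}
    pair_idx = np.asarray([[idx[p.id_a], idx[p.id_b]] for p in pairs])
    seed_seqs = np.random.SeedSequence(cfg.seed).spawn(len(inputs.gmap.chromosomes))

    sp_rows, mp_rows, grid_frames = [], [], []
    null_blocks: list[np.ndarray] = []  # each (n_loci_block, n_reps)
    obs_z: list[float] = []
    degenerate: list[str] = []
    locus_counter = 0
    locus_slices: list[tuple[str, str, int]] = []  # (table, key, row index)

    for chrom, sseq in zip(inputs.gmap.chromosomes, seed_seqs):
        markers = [m for m in inputs.gmap.markers(chrom) if m in set(panel.markers)]
        if not markers:
            continue
        pos = np.asarray([inputs.gmap.position_of(m) for m in markers])
        labels = [inputs.freqs.alleles(m) for m in markers]
        probs = [inputs.freqs._probs[m] for m in markers]
        thetas = np.atleast_1d(haldane_theta(np.diff(pos)))
        rng = np.random.default_rng(sseq)
        geno_null = drop_linked_batch(inputs.ped, labels, probs, thetas, cfg.n_reps, rng)

        obs_geno = np.zeros((len(inputs.ped), len(markers), 2), dtype=np.int64)
        for k, m in enumerate(markers):
            mcol = panel.geno[:, panel._midx[m], :]
            for iid, g in zip(panel.ids, mcol):
                obs_geno[idx[iid], k, :] = g
        lookups = [inputs.freqs.weight_lookup(m, weight.form) for m in markers]
        scorer = PairScorer(obs_geno, pair_idx, lookups)
        obs_scores = scorer.observed()
        null_scores = scorer.score(geno_null)  # (R, M)

        ok = null_scores.std(axis=0, ddof=1) > 0
        degenerate.extend([m for m, good in zip(markers, ok) if not good])
        keep = np.flatnonzero(ok)
        if keep.size == 0:
            continue
        markers = [markers[k] for k in keep]
        pos = pos[keep]
        obs_scores = obs_scores[keep]
        null_scores = null_scores[:, keep]
        n_inf = scorer.n_informative[keep]

        # singlepoint
        for k, m in enumerate(markers):
            z, p_asym, p_emp = z_and_pvalues(
                obs_scores[k], null_scores[:, k], cfg.empirical_convention
            )
            sp_rows.append(
                {
                    "chrom": chrom,
                    "marker": m,
                    "position_cM": pos[k],
                    "observed": obs_scores[k],
                    "null_mean": null_scores[:, k].mean(),
                    "null_sd": null_scores[:, k].std(ddof=1),
                    "Z": z,
                    "p_asymptotic": p_asym,
                    "p_empirical": p_emp,
                    "n_pairs": int(n_inf[k]),
                    "n_reps": cfg.n_reps,
                }
            )
            obs_z.append(z)
            locus_slices.append(("singlepoint", m, len(sp_rows) - 1))
        null_blocks.append(null_scores.T)
        locus_counter += len(markers)

        # multipoint windows centred on each marker
        for k, m in enumerate(markers):
            widx = np.flatnonzero(np.abs(pos - pos[k]) <= cfg.window_cm)
            res = multipoint_window(
                obs_scores, null_scores, widx, cfg.empirical_convention
            )
            null_blocks.append(res.pop("null_scores")[None, :])
            mp_rows.append(
                {
                    "chrom": chrom,
                    "marker": m,
                    "position_cM": pos[k],
                    "n_window_markers": int(widx.size),
                    **res,
                    "n_reps": cfg.n_reps,
                }
            )
            obs_z.append(res["Z"])
            locus_slices.append(("multipoint", m, len(mp_rows) - 1))

        # interpolation grid
        gdf, grid, null_grid = grid_multipoint(
            obs_scores, null_scores, pos, cfg.grid_step_cm, cfg.empirical_convention
        )
        gdf.insert(0, "chrom", chrom)
        grid_frames.append(gdf)
        null_blocks.append(null_grid.T)
        obs_z.extend(gdf["Z"].tolist())
        locus_slices.extend(
            ("grid", f"{chrom}:{p:.2f}", i) for i, p in enumerate(gdf["position_cM"])
        )

    if not sp_rows:
        raise ScanAbort("every marker produced a degenerate null; nothing to report")

    all_null = np.vstack(null_blocks)  # (n_loci, n_reps)
    adj = genomewide_adjust(np.asarray(obs_z), all_null)

    singlepoint = pd.DataFrame(sp_rows)
    multipoint = pd.DataFrame(mp_rows)
    grid_df = pd.concat(grid_frames, ignore_index=True)
    grid_offset = {}
    pos_in_grid = 0
    for k, (table, key, row) in enumerate(locus_slices):
        if table == "singlepoint":
            singlepoint.loc[row, "p_adjusted"] = adj[k]
        elif table == "multipoint":
            multipoint.loc[row, "p_adjusted"] = adj[k]
        else:
            grid_df.loc[pos_in_grid, "p_adjusted"] = adj[k]
            pos_in_grid += 1

    regions = summarize_regions(grid_df, cfg.region_p_threshold)
    return ScanResults(
        singlepoint=singlepoint,
        multipoint=multipoint,
        grid=grid_df,
        regions=regions,
        qc=qc.reset_index(),
        n_affected=len(affected),
        n_pairs=len(pairs),
        degenerate_markers=degenerate,
        metadata={
            "seed": cfg.seed,
            "n_reps": cfg.n_reps,
            "weight_form": cfg.weight_form,
            "selection_mode": cfg.selection_mode,
            "el_min": rule.el_min,
            "fel_min": rule.fel_min,
            "age_min": rule.age_min,
            "window_cm": cfg.window_cm,
            "grid_step_cm": cfg.grid_step_cm,
            "call_rate_threshold": cfg.call_rate_threshold,
            "region_p_threshold": cfg.region_p_threshold,
        },
    )


def summarize_regions(grid: pd.DataFrame, p_threshold: float = 0.01) -> pd.DataFrame:
    """Contiguous grid runs with nominal (asymptotic) p below threshold,
    summarised per chromosome as Low/High cM, max Z, min p, and the run's
    smallest adjusted p.  Runs never merge across chromosomes."""
    rows = []
    for chrom, sub in grid.groupby("chrom", sort=False):
        sub = sub.sort_values("position_cM").reset_index(drop=True)
        hot = (sub["p_asymptotic"] < p_threshold).to_numpy()
        if not hot.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = sub.iloc[start:stop]
            rows.append(
                {
                    "chrom": chrom,
                    "low_cM": run["position_cM"].min(),
                    "high_cM": run["position_cM"].max(),
                    "max_Z": run["Z"].max(),
                    "min_p": run["p_asymptotic"].min(),
                    "p_adjusted": (
                        run["p_adjusted"].min() if "p_adjusted" in run else np.nan
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "low_cM", "high_cM", "max_Z", "min_p", "p_adjusted"]
    )


def write_report(results: ScanResults, out_dir) -> dict[str, Path]:
    """Write singlepoint/multipoint/grid/region/QC TSVs with a run-metadata
    comment header; cM coordinates carry 2-decimal precision."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = results.metadata
    header = "# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n"
    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df = df.copy()
        for col in df.columns:
            if col.endswith("_cM") or col == "position_cM":
                df[col] = df[col].map(lambda v: f"{v:.2f}")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        paths[name] = path

    _write("singlepoint", results.singlepoint)
    _write("multipoint", results.multipoint)
    _write("grid", results.grid)
    _write("regions", results.regions)
    _write("qc", results.qc)
    return paths
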