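"""Calibration and validation studies run on synthetic data.

These routines define the package's standard evaluation conditions — a
null-calibration scan, a scaled-down power/localization run, a Monte Carlo
cross-check of kinship coefficients against gene-drop IBD estimates, an
ascertainment-threshold monotonicity check, and an end-to-end determinism
check — and are used both by the test suite and by the reproduction script.

Problem sizes are desk-scale by design: ~600-750 individuals per study,
100-500 Monte Carlo replicates, and a causal allele frequency of 0.05 in
power runs (the design-truth frequency of 0.01 would require far larger
pedigrees to yield enough carrier pairs).
"""

from __future__ import annotations

import dataclasses
import filecmp
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genedrop import AlleleFrequencyTable, drop_unlinked_batch, estimate_ibd
from .linkage import PairScorer
from .pedigree import Individual, Pedigree, enumerate_affected_pairs, validate_pedigree
from .phenotype import compute_phenotypes, quartile_thresholds
from .pipeline import ScanConfig, StudyInputs, read_study_inputs, run_scan, write_report
from .simulate import SimConfig, make_scan_fixture, simulate_lifespans, simulate_pedigree

__all__ = [
    "null_calibration",
    "power_localization",
    "pair_class_fixture",
    "ibd_kinship_agreement",
    "ascertainment_monotonicity",
    "determinism_check",
    "NULL_CALIBRATION_CONFIG",
    "POWER_CONFIG",
    "MONOTONICITY_CONFIG",
]

# ~600-700 members across 20 kindreds; no causal effect (HR = 1)
NULL_CALIBRATION_CONFIG = SimConfig(
    n_founder_couples=20,
    n_generations=4,
    mean_offspring=2.8,
    hazard_ratio=1.0,
    causal_allele_freq=0.05,
)

# scaled-down power run: dominant allele, frequency 0.05, HR 0.5, at 50 cM
# on a single 150 cM chromosome.  Kindreds are shallow with large sibships
# (historical high-fertility families): close relative pairs concentrate the
# causal haplotype, and few founders per kindred keep carrier origins
# mostly single, which is what the sharing statistic can see.
POWER_CONFIG = SimConfig(
    n_founder_couples=30,
    n_generations=3,
    mean_offspring=6.0,
    causal_allele_freq=0.05,
    hazard_ratio=0.5,
    chrom_lengths_cm=(150.0,),
    causal_chrom="1",
    causal_position_cm=50.0,
)

# a large fixed study so the attained-age 95/98/100 progression is populated
MONOTONICITY_CONFIG = SimConfig(
    n_founder_couples=40,
    n_generations=4,
    mean_offspring=3.5,
    causal_allele_freq=0.05,
    hazard_ratio=0.5,
)


def null_calibration(
    seed: int,
    n_markers: int = 100,
    n_reps: int = 500,
    cfg: SimConfig = NULL_CALIBRATION_CONFIG,
    missingness: float = 0.05,
) -> dict:
    """Empirical p-values of unlinked markers scanned under the null.

    Simulates a multi-kindred study with no genetic effect on lifespan,
    selects affected individuals by top-quartile EL and FEL, and scores
    ``n_markers`` unlinked microsatellite-like markers whose observed
    genotypes are themselves one gene-drop replicate, against ``n_reps``
    further replicates.  Under this exchangeability the empirical p-values
    are uniform up to Monte Carlo granularity.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    ped = simulate_pedigree(cfg, np.random.default_rng(ss[0]))
    ages = simulate_lifespans(ped, {}, cfg, np.random.default_rng(ss[1]))
    members = [
        dataclasses.replace(ind, attained_age=ages[ind.id]) for ind in ped.members
    ]
    ped = validate_pedigree(members)

    from .simulate import _expected_lifespan_table

    phen = compute_phenotypes(ped, _expected_lifespan_table(cfg))
    el_min = quartile_thresholds(phen["EL"].dropna())
    fel_min = quartile_thresholds(phen["FEL"].dropna())
    affected = set(
        phen.index[(phen["EL"] >= el_min) & (phen["FEL"] >= fel_min)].tolist()
    )
    pairs = enumerate_affected_pairs(ped, affected)
    if not pairs:
        raise RuntimeError("null calibration study produced no affected pairs")

    rng = np.random.default_rng(ss[2])
    markers = [f"M{i}" for i in range(n_markers)]
    freq_map = {}
    for m in markers:
        k = int(rng.integers(4, 15))
        p = rng.dirichlet(np.ones(k))
        p = np.maximum(p, 0.005)
        p /= p.sum()
        freq_map[m] = {a + 1: float(p[a]) for a in range(k)}
    freqs = AlleleFrequencyTable(freq_map)

    obs = drop_unlinked_batch(ped, freqs, markers, 1, rng)[0]
    miss = rng.random(obs.shape[:2]) < missingness
    obs[miss] = 0

    null = drop_unlinked_batch(
        ped, freqs, markers, n_reps, np.random.default_rng(ss[3])
    )
    idx = {iid: k for k, iid in enumerate(ped.ids)}
    pair_idx = np.asarray([[idx[p.id_a], idx[p.id_b]] for p in pairs])
    lookups = [freqs.weight_lookup(m, "inverse_sqrt") for m in markers]
    scorer = PairScorer(obs, pair_idx, lookups)
    obs_scores = scorer.observed()
    null_scores = scorer.score(null)  # (R, M)
    pvals = (null_scores >= obs_scores[None, :]).mean(axis=0)

    frac = float((pvals <= 0.05).mean())
    ks = sps.kstest(pvals, "uniform")
    lo, hi = sps.binom.interval(0.99, n_markers, 0.05)
    return {
        "pvalues": pvals,
        "fraction_p_le_05": frac,
        "binom99_lo": lo / n_markers,
        "binom99_hi": hi / n_markers,
        "ks_pvalue": float(ks.pvalue),
        "n_pairs": len(pairs),
        "n_affected": len(affected),
        "n_individuals": len(ped),
    }


def _scan_study(cfg: SimConfig, seed: int, n_reps: int) -> tuple:
    study = make_scan_fixture(cfg, seed)
    scan_cfg = ScanConfig(
        n_reps=n_reps, seed=seed + 1, selection_mode="el_fel_quartile"
    )
    inputs = StudyInputs(
        study.ped, study.panel, study.gmap, study.freqs,
        study.phenotypes, study.el_table, scan_cfg,
    )
    return study, run_scan(inputs)


def power_localization(
    seed: int,
    n_replicates: int = 20,
    n_reps: int = 250,
    cfg: SimConfig = POWER_CONFIG,
) -> dict:
    """Scaled-down parameter-recovery run.

    For ``n_replicates`` seeded studies with the causal allele present,
    records whether the genome-wide maximum grid Z falls within 20 cM of
    the causal position, and compares the median peak Z against the 95th
    percentile of genome-wide peak Z from matched HR = 1 (null) studies.
    """
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**30))
    hits, peak_z, peak_dist = [], [], []
    for r in range(n_replicates):
        _, res = _scan_study(cfg, base + r, n_reps)
        top = res.grid.loc[res.grid["Z"].idxmax()]
        on_causal = str(top["chrom"]) == cfg.causal_chrom
        dist = abs(top["position_cM"] - cfg.causal_position_cm)
        hits.append(bool(on_causal and dist <= 20.0))
        peak_z.append(float(top["Z"]))
        peak_dist.append(float(dist) if on_causal else float("inf"))

    null_cfg = dataclasses.replace(cfg, hazard_ratio=1.0)
    null_peaks = []
    for r in range(n_replicates):
        _, res = _scan_study(null_cfg, base + 10_000 + r, n_reps)
        null_peaks.append(float(res.grid["Z"].max()))

    return {
        "hit_fraction": float(np.mean(hits)),
        "median_peak_z": float(np.median(peak_z)),
        "null_peak_95": float(np.quantile(null_peaks, 0.95)),
        "peak_z": peak_z,
        "null_peaks": null_peaks,
        "peak_distance_cm": peak_dist,
        "n_replicates": n_replicates,
    }


def pair_class_fixture() -> tuple[Pedigree, dict[str, tuple[str, str]]]:
    """A fixture pedigree containing the classic relative-pair classes:
    parent-offspring, full sibs, avuncular, first cousins, and double first
    cousins (two brothers married to two sisters)."""
    m = Individual
    members = [
        m("gpA", sex="male"), m("gmA", sex="female"),
        m("gpB", sex="male"), m("gmB", sex="female"),
        # two brothers from family A
        m("bro1", "gpA", "gmA", "male"), m("bro2", "gpA", "gmA", "male"),
        # a sister from family A (for avuncular / cousin branches)
        m("sisA", "gpA", "gmA", "female"),
        # two sisters from family B
        m("sis1", "gpB", "gmB", "female"), m("sis2", "gpB", "gmB", "female"),
        # brothers marry sisters: children are double first cousins
        m("dfc1", "bro1", "sis1", "male"), m("dfc2", "bro2", "sis2", "female"),
        # sisA marries in; her child is a first cousin of ord1's child
        m("husC", sex="male"), m("nieceA", "husC", "sisA", "female"),
        # ordinary first cousins: children of sisA and of bro1
        m("wifeD", sex="female"), m("cousB", "bro1", "wifeD", "male"),
    ]
    ped = validate_pedigree(members)
    pairs = {
        "parent_offspring": ("gpA", "bro1"),
        "full_sib": ("bro1", "bro2"),
        "avuncular": ("bro2", "nieceA"),
        "first_cousin": ("nieceA", "cousB"),
        "double_first_cousin": ("dfc1", "dfc2"),
    }
    return ped, pairs


def ibd_kinship_agreement(seed: int, n_reps: int = 10_000) -> pd.DataFrame:
    """Gene-drop IBD estimates vs 2*phi for each fixture pair class.

    The Monte Carlo SE comes from the per-replicate variance of the shared
    proportion, and the deviation of the estimate from the pedigree kinship
    is reported in SE units (parent-offspring pairs share exactly one
    allele every replicate, so their SE is zero and their deviation 0).
    """
    ped, pairs = pair_class_fixture()
    rows = []
    ss = np.random.SeedSequence(seed)
    for (cls, (i, j)), sseq in zip(pairs.items(), ss.spawn(len(pairs))):
        est, se = estimate_ibd(ped, i, j, n_reps, sseq, return_se=True)
        expected = 2.0 * ped.kinship(i, j)
        rows.append(
            {
                "pair_class": cls,
                "expected_2phi": expected,
                "ibd_estimate": est,
                "mc_se": se,
                "deviation_se": abs(est - expected) / se if se > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def ascertainment_monotonicity(
    seed: int, cfg: SimConfig = MONOTONICITY_CONFIG,
    thresholds: tuple[float, ...] = (95.0, 98.0, 100.0),
) -> pd.DataFrame:
    """Affected counts and affected-pair counts as the attained-age
    threshold rises through 95/98/100 on one fixed synthetic study."""
    study = make_scan_fixture(cfg, seed)
    ages = study.phenotypes["attained_age"]
    rows = []
    for thr in thresholds:
        affected = set(ages.index[ages >= thr])
        pairs = enumerate_affected_pairs(study.ped, affected)
        rows.append(
            {"age_min": thr, "n_affected": len(affected), "n_pairs": len(pairs)}
        )
    return pd.DataFrame(rows)


def determinism_check(seed: int, work_dir: Path | str, n_reps: int = 100) -> bool:
    """Two end-to-end runs (files on disk, same seed) are byte-identical."""
    work = Path(work_dir)
    cfg = SimConfig(
        n_founder_couples=12, n_generations=3, mean_offspring=4.0,
        causal_allele_freq=0.1, chrom_lengths_cm=(60.0,), causal_chrom="1",
        causal_position_cm=30.0,
    )
    study_dir = work / "study"
    make_scan_fixture(cfg, seed, out_dir=study_dir)
    outputs = []
    for run in ("run1", "run2"):
        inputs = read_study_inputs(
            study_dir / "study.ped",
            study_dir / "study.map",
            study_dir / "study.phen.tsv",
            study_dir / "study.expected.tsv",
            freq_path=study_dir / "study.freq.tsv",
            config=ScanConfig(
                n_reps=n_reps, seed=seed, selection_mode="el_fel_quartile"
            ),
        )
        results = run_scan(inputs)
        outputs.append(write_report(results, work / run))
    for name in outputs[0]:
        same = filecmp.cmp(outputs[0][name], outputs[1][name], shallow=False)
        if not same:
            return False
    return True
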