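"""Synthetic multigenerational studies with a latent longevity allele.

The generator emulates the structure the linkage analysis assumes: deep
pedigrees with large sibships founded by unrelated couples (married-in
spouses keep them non-inbred), a multiallelic microsatellite panel at ~3.4
cM spacing dropped through the pedigree with Haldane recombination, a
biallelic causal locus (default: autosomal dominant, allele frequency 0.01)
whose carriers enjoy a reduced all-cause mortality hazard (default hazard
ratio 0.5 on a Gompertz baseline), and per-call genotyping missingness.

It also evaluates ascertainment designs: for a candidate affected-selection
rule it estimates the probability a selected subject carries the longevity
allele (positive predictive value) and the probability a carrier is
selected (sensitivity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import integrate

from .genedrop import AlleleFrequencyTable, GeneticMap, drop_linked_batch, haldane_theta
from .io import (
    GenotypePanel,
    write_expected_lifespans,
    write_frequencies,
    write_map,
    write_ped,
    write_phenotypes,
)
from .pedigree import Individual, Pedigree, validate_pedigree
from .phenotype import ExpectedLifespanTable, SelectionRule, compute_phenotypes, \
    quartile_thresholds, select_affected

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_lifespans",
    "gompertz_mean",
    "gompertz_quantile",
    "evaluate_selection_design",
    "make_scan_fixture",
]

_CAUSAL_NORMAL = 1
_CAUSAL_LONGEVITY = 2


@dataclass(frozen=True)
class SimConfig:
    """Study-generator configuration.

    Defaults encode the design assumptions of the analysis: a dominant
    longevity allele at frequency 0.01 with an all-cause mortality hazard
    ratio of 0.5, microsatellite-like markers averaging 3.4 cM spacing with
    2-38 alleles each, and Gompertz baseline mortality placing non-carrier
    modal ages in the mid-80s so extreme survivors land in the observed
    86-109 range.  ``causal_allele_freq`` may be raised (e.g. to 0.05) for
    desk-scale power runs, where 0.01 would demand very large pedigrees.
    """

    n_founder_couples: int = 10
    n_generations: int = 4
    mean_offspring: float = 3.5
    offspring_dispersion: Optional[float] = None  # None = Poisson; 0 = deterministic
    causal_allele_freq: float = 0.01
    inheritance: str = "dominant"
    hazard_ratio: float = 0.5
    gompertz_a: float = 1e-4  # baseline hazard/yr at age 0 (female)
    gompertz_b: float = 0.085  # hazard doubling ~every 8 yr
    male_hazard_multiplier: float = 1.35
    chrom_lengths_cm: tuple[float, ...] = (150.0, 150.0)
    marker_spacing_cm: float = 3.4
    allele_count_range: tuple[int, int] = (2, 38)
    dirichlet_concentration: float = 1.0
    missingness_rate: float = 0.05
    causal_chrom: str = "1"
    causal_position_cm: float = 75.0
    birth_year_start: int = 1850
    generation_gap_years: int = 28

    def __post_init__(self) -> None:
        if self.mean_offspring <= 0:
            raise ValueError("mean offspring count must be positive")
        if not 0 < self.causal_allele_freq < 1:
            raise ValueError("causal allele frequency must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.inheritance not in ("dominant", "additive", "recessive"):
            raise ValueError(f"unknown inheritance model {self.inheritance!r}")
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ValueError("Gompertz parameters must be positive")
        if self.marker_spacing_cm <= 0:
            raise ValueError("marker spacing must be positive")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness rate must be in [0, 1)")
        lo, hi = self.allele_count_range
        if lo < 2 or hi < lo:
            raise ValueError("allele-count range must satisfy 2 <= lo <= hi")
        if self.n_generations < 2 or self.n_founder_couples < 1:
            raise ValueError("need >= 2 generations and >= 1 founder couple")


@dataclass
class SimulatedStudy:
    """One simulated study bundle: pedigree, marker panel, causal truth,
    lifespans, and the expected-lifespan table used to score EL."""

    ped: Pedigree
    panel: GenotypePanel
    gmap: GeneticMap
    freqs: AlleleFrequencyTable
    causal_copies: dict[str, int]
    carriers: set[str]
    causal_chrom: str
    causal_position_cm: float
    el_table: ExpectedLifespanTable
    phenotypes: pd.DataFrame
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def _n_offspring(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.offspring_dispersion == 0:
        return int(round(cfg.mean_offspring))
    if cfg.offspring_dispersion is None:
        return int(rng.poisson(cfg.mean_offspring))
    # negative binomial with variance mean * (1 + dispersion)
    mean, disp = cfg.mean_offspring, cfg.offspring_dispersion
    n = mean / disp
    p = 1.0 / (1.0 + disp)
    return int(rng.negative_binomial(n, p))


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | int) -> Pedigree:
    """Random multigeneration pedigree forest.

    Each founder couple heads a kindred; lineage members of intermediate
    generations marry new (married-in) founders, so kindreds stay connected
    but non-inbred.  The final generation does not reproduce.
    """
    rng = np.random.default_rng(rng)
    members: list[Individual] = []

    def byear(gen: int) -> int:
        return int(cfg.birth_year_start + gen * cfg.generation_gap_years
                   + rng.integers(-4, 5))

    for k in range(cfg.n_founder_couples):
        father = Individual(id=f"K{k}G0F", sex="male", birth_year=byear(0))
        mother = Individual(id=f"K{k}G0M", sex="female", birth_year=byear(0))
        members.extend([father, mother])
        couples = [(father.id, mother.id)]
        counter = 0
        for gen in range(1, cfg.n_generations):
            next_couples = []
            for fid, mid in couples:
                for _ in range(_n_offspring(cfg, rng)):
                    counter += 1
                    sex = "male" if rng.random() < 0.5 else "female"
                    child = Individual(
                        id=f"K{k}G{gen}I{counter}",
                        father_id=fid,
                        mother_id=mid,
                        sex=sex,
                        birth_year=byear(gen),
                    )
                    members.append(child)
                    if gen < cfg.n_generations - 1:
                        spouse = Individual(
                            id=f"K{k}G{gen}S{counter}",
                            sex="female" if sex == "male" else "male",
                            birth_year=byear(gen),
                        )
                        members.append(spouse)
                        pair = (
                            (child.id, spouse.id) if sex == "male" else (spouse.id, child.id)
                        )
                        next_couples.append(pair)
            couples = next_couples
    return validate_pedigree(members)


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _build_map(cfg: SimConfig) -> GeneticMap:
    rows = []
    for c, length in enumerate(cfg.chrom_lengths_cm, start=1):
        n = max(int(round(length / cfg.marker_spacing_cm)) + 1, 2)
        for i, pos in enumerate(np.linspace(0.0, length, n)):
            rows.append({"chrom": str(c), "marker": f"C{c}M{i + 1}", "cM": float(pos)})
    return GeneticMap(pd.DataFrame(rows))


def _marker_frequencies(cfg: SimConfig, gmap: GeneticMap,
                        rng: np.random.Generator) -> AlleleFrequencyTable:
    freqs: dict[str, dict[int, float]] = {}
    lo, hi = cfg.allele_count_range
    for chrom in gmap.chromosomes:
        for m in gmap.markers(chrom):
            k = int(rng.integers(lo, hi + 1))
            p = rng.dirichlet(np.full(k, cfg.dirichlet_concentration))
            # frequencies rarer than ~1/2 of a control sample's chromosomes
            # would never be estimable by counting; flooring also keeps the
            # 1/q sharing weights from exploding on phantom-rare alleles
            p = np.maximum(p, 0.005)
            p = p / p.sum()
            freqs[m] = {a + 1: float(p[a]) for a in range(k)}
    return AlleleFrequencyTable(freqs)


def simulate_genotypes(
    ped: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator | int,
    gmap: Optional[GeneticMap] = None,
    freqs: Optional[AlleleFrequencyTable] = None,
) -> tuple[GenotypePanel, GeneticMap, AlleleFrequencyTable, dict[str, int]]:
    """Drop the marker panel plus the (hidden) causal locus through ``ped``.

    Founder haplotypes are at linkage equilibrium; the causal locus is
    transmitted linked at its configured map position but excluded from the
    returned panel; per-call missingness applies to markers only, never to
    the causal truth.  Returns (panel, map, frequency table, causal copy
    number per individual).
    """
    rng = np.random.default_rng(rng)
    gmap = gmap or _build_map(cfg)
    freqs = freqs or _marker_frequencies(cfg, gmap, rng)
    ids = ped.ids
    n_ind = len(ids)
    panel_markers: list[str] = []
    panel_cols: list[np.ndarray] = []
    causal_geno: Optional[np.ndarray] = None

    for chrom in gmap.chromosomes:
        markers = gmap.markers(chrom)
        pos = gmap.positions(chrom)
        labels = [freqs.alleles(m) for m in markers]
        probs = [freqs._probs[m] for m in markers]
        if chrom == cfg.causal_chrom:
            ins = int(np.searchsorted(pos, cfg.causal_position_cm))
            pos = np.insert(pos, ins, cfg.causal_position_cm)
            labels.insert(ins, np.asarray([_CAUSAL_NORMAL, _CAUSAL_LONGEVITY]))
            probs.insert(
                ins,
                np.asarray([1.0 - cfg.causal_allele_freq, cfg.causal_allele_freq]),
            )
            causal_idx = ins
        else:
            causal_idx = None
        thetas = np.atleast_1d(haldane_theta(np.diff(pos)))
        geno = drop_linked_batch(ped, labels, probs, thetas, 1, rng)[0]
        if causal_idx is not None:
            causal_geno = geno[:, causal_idx, :]
            geno = np.delete(geno, causal_idx, axis=1)
            markers = list(markers)
        panel_markers.extend(markers)
        panel_cols.append(geno)

    geno_all = np.concatenate(panel_cols, axis=1)
    if cfg.missingness_rate > 0:
        miss = rng.random((n_ind, geno_all.shape[1])) < cfg.missingness_rate
        geno_all[miss] = 0
    panel = GenotypePanel(ids, panel_markers, geno_all)
    if causal_geno is None:
        raise ValueError(
            f"causal chromosome {cfg.causal_chrom!r} not present in the map"
        )
    copies = {
        iid: int((causal_geno[k] == _CAUSAL_LONGEVITY).sum()) for k, iid in enumerate(ids)
    }
    return panel, gmap, freqs, copies


def _carriers(copies: Mapping[str, int], inheritance: str) -> set[str]:
    if inheritance == "recessive":
        return {i for i, c in copies.items() if c == 2}
    return {i for i, c in copies.items() if c >= 1}


# ---------------------------------------------------------------------------
# lifespans
# ---------------------------------------------------------------------------

def _hazard_factor(copies: int, cfg: SimConfig) -> float:
    hr = cfg.hazard_ratio
    if cfg.inheritance == "dominant":
        return hr if copies >= 1 else 1.0
    if cfg.inheritance == "recessive":
        return hr if copies == 2 else 1.0
    return hr**copies  # additive: HR per copy


def gompertz_quantile(p: float, a: float, b: float) -> float:
    """Age by which a fraction ``p`` of a Gompertz(a, b) cohort has died."""
    return np.log1p(-b * np.log1p(-p) / a) / b


def gompertz_mean(a: float, b: float) -> float:
    """Mean Gompertz(a, b) lifespan (numerical survival integral)."""
    surv = lambda t: np.exp(-(a / b) * np.expm1(b * t))
    val, _ = integrate.quad(surv, 0, 150.0, limit=200)
    return float(val)


def simulate_lifespans(
    ped: Pedigree,
    causal_copies: Mapping[str, int],
    cfg: SimConfig,
    rng: np.random.Generator | int,
) -> dict[str, float]:
    """Attained ages by inverse-transform sampling of a Gompertz
    proportional-hazards model: carriers' hazards are multiplied by the
    configured hazard ratio (model-dependent on copy number)."""
    rng = np.random.default_rng(rng)
    ages = {}
    for iid in ped.ids:
        ind = ped[iid]
        a = cfg.gompertz_a * (
            cfg.male_hazard_multiplier if ind.sex == "male" else 1.0
        )
        a *= _hazard_factor(causal_copies.get(iid, 0), cfg)
        u = rng.random()
        age = np.log1p(-cfg.gompertz_b * np.log(u) / a) / cfg.gompertz_b
        ages[iid] = round(float(age), 2)
    return ages


# ---------------------------------------------------------------------------
# study assembly and design evaluation
# ---------------------------------------------------------------------------

def _expected_lifespan_table(cfg: SimConfig) -> ExpectedLifespanTable:
    """Non-carrier Gompertz mean lifespan per sex, one all-cohort band
    (the simulation has no secular mortality trend)."""
    return ExpectedLifespanTable.constant(
        {
            "female": gompertz_mean(cfg.gompertz_a, cfg.gompertz_b),
            "male": gompertz_mean(
                cfg.gompertz_a * cfg.male_hazard_multiplier, cfg.gompertz_b
            ),
        }
    )


def make_scan_fixture(
    cfg: SimConfig,
    seed: int,
    out_dir: Optional[Path | str] = None,
) -> SimulatedStudy:
    """One bundled, seeded study: pedigree, genotypes, lifespans, phenotype
    table, and the expected-lifespan table; optionally written to disk in
    the pipeline's input formats."""
    ss = np.random.SeedSequence(seed)
    rng_ped, rng_geno, rng_life = (np.random.default_rng(s) for s in ss.spawn(3))
    ped = simulate_pedigree(cfg, rng_ped)
    panel, gmap, freqs, copies = simulate_genotypes(ped, cfg, rng_geno)
    ages = simulate_lifespans(ped, copies, cfg, rng_life)
    members = [
        dataclasses.replace(
            ind,
            attained_age=ages[ind.id],
            death_year=(
                int(ind.birth_year + ages[ind.id]) if ind.birth_year is not None else None
            ),
        )
        for ind in ped.members
    ]
    ped = validate_pedigree(members)
    el_table = _expected_lifespan_table(cfg)
    phen = pd.DataFrame(
        {
            "id": ped.ids,
            "sex": [ped[i].sex for i in ped.ids],
            "birth_year": [ped[i].birth_year for i in ped.ids],
            "death_year": [ped[i].death_year for i in ped.ids],
            "attained_age": [ped[i].attained_age for i in ped.ids],
        }
    ).set_index("id")
    study = SimulatedStudy(
        ped=ped,
        panel=panel,
        gmap=gmap,
        freqs=freqs,
        causal_copies=copies,
        carriers=_carriers(copies, cfg.inheritance),
        causal_chrom=cfg.causal_chrom,
        causal_position_cm=cfg.causal_position_cm,
        el_table=el_table,
        phenotypes=phen,
        seed=seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"synthetic study, seed={seed}"
        write_ped(ped, panel, out / "study.ped", header=tag)
        write_map(gmap, out / "study.map", header=tag)
        write_frequencies(freqs, out / "study.freq.tsv", header=tag)
        write_phenotypes(phen, out / "study.phen.tsv", header=tag)
        write_expected_lifespans(el_table, out / "study.expected.tsv", header=tag)
    return study


def evaluate_selection_design(
    cfg: SimConfig,
    rule: SelectionRule,
    n_sim: int,
    seed: int = 0,
    use_quartiles: bool = False,
) -> dict[str, float]:
    """Monte Carlo evaluation of an ascertainment rule.

    Over ``n_sim`` simulated studies, estimates PPV = P(carrier | selected)
    and sensitivity = P(selected | carrier) with binomial standard errors.
    With ``use_quartiles`` the EL/FEL thresholds are re-derived per study as
    top-quartile cutoffs (attained-age rules are applied as given).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    ss = np.random.SeedSequence(seed)
    n_sel_car = n_sel = n_car = n_tot = 0
    for child in ss.spawn(n_sim):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        study = make_scan_fixture(cfg, sub_seed)
        phen = compute_phenotypes(study.ped, study.el_table)
        phen["attained_age"] = study.phenotypes["attained_age"]
        active = rule
        if use_quartiles and rule.mode == "el_fel_thresholds":
            active = SelectionRule(
                mode="el_fel_thresholds",
                el_min=quartile_thresholds(phen["EL"].dropna()),
                fel_min=(
                    quartile_thresholds(phen["FEL"].dropna())
                    if rule.fel_min > -1e6  # very low = "EL-only" rule: keep it
                    else rule.fel_min
                ),
            )
        selected = select_affected(phen, active)
        carriers = study.carriers
        n_sel += len(selected)
        n_car += len(carriers)
        n_tot += len(study.ped)
        n_sel_car += len(selected & carriers)
    ppv = n_sel_car / n_sel if n_sel else float("nan")
    sens = n_sel_car / n_car if n_car else float("nan")
    return {
        "ppv": ppv,
        "ppv_se": float(np.sqrt(ppv * (1 - ppv) / n_sel)) if n_sel else float("nan"),
        "sensitivity": sens,
        "sensitivity_se": (
            float(np.sqrt(sens * (1 - sens) / n_car)) if n_car else float("nan")
        ),
        "n_selected": n_sel,
        "n_carriers": n_car,
        "n_individuals": n_tot,
        "carrier_prevalence": n_car / n_tot if n_tot else float("nan"),
    }
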