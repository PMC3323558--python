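"""APM linkage statistics: sharing scores, Monte Carlo nulls, multipoint
scans, genome-wide adjustment, and Z-score meta-analysis.

The affected-pedigree-member (APM) statistic sums, over all pairs of
affected relatives, an allele-frequency-weighted count of alleles shared
identical by state:

    S_ij = 1/4 * sum_a sum_b  delta(G_ia, G_jb) * f(q(G_ia))

where delta is the Kronecker delta and f an allele-frequency weight
(1, 1/sqrt(q) or 1/q; rare shared alleles are the more surprising, hence
the up-weighting).  Significance comes from a gene-dropping Monte Carlo
null; multipoint statistics sum S_ij over adjacent markers against a null
dropped with inter-marker recombination, so the null joint law matches the
map.  Experiment-wise p-values compare each observed Z to the distribution
of genome-wide maximum null Z (Churchill-Doerge style); Z curves from
independent studies combine by the weighted mean Z-score rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genedrop import (
    MISSING,
    AlleleFrequencyTable,
    GeneticMap,
    drop_linked_batch,
    drop_unlinked_batch,
    haldane_theta,
)
from .pedigree import Pedigree, RelativePair

__all__ = [
    "SharingWeight",
    "MetaInput",
    "DegenerateNullError",
    "sharing_statistic",
    "apm_observed",
    "PairScorer",
    "null_distribution",
    "z_and_pvalues",
    "multipoint_window",
    "grid_multipoint",
    "grid_weights",
    "genomewide_adjust",
    "meta_combine",
]


class DegenerateNullError(RuntimeError):
    """The Monte Carlo null has zero variance (e.g. a marker monomorphic in
    founders); no Z-score can be formed."""


@dataclass(frozen=True)
class SharingWeight:
    """Allele-frequency weight f(q) applied to each shared allele.

    ``inverse_sqrt`` (f = 1/sqrt(q)) is the classical Weeks-Lange choice and
    the default; ``constant`` (f = 1) and ``inverse`` (f = 1/q) are also
    available for sensitivity analyses.
    """

    form: str = "inverse_sqrt"

    def __post_init__(self) -> None:
        if self.form not in ("constant", "inverse_sqrt", "inverse"):
            raise ValueError(f"unknown sharing-weight form {self.form!r}")

    def f(self, q):
        q = np.asarray(q, dtype=float)
        if self.form == "constant":
            out = np.ones_like(q)
        elif self.form == "inverse_sqrt":
            out = 1.0 / np.sqrt(q)
        else:
            out = 1.0 / q
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetaInput:
    """One study's Z curve along a chromosome, for meta-analysis."""

    label: str
    positions_cm: np.ndarray
    z: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if pos.shape != z.shape or pos.ndim != 1:
            raise ValueError("positions and Z must be 1-D arrays of equal length")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted")
        if self.weight <= 0:
            raise ValueError("study weight must be positive")
        object.__setattr__(self, "positions_cm", pos)
        object.__setattr__(self, "z", z)


# ---------------------------------------------------------------------------
# the sharing statistic
# ---------------------------------------------------------------------------

def sharing_statistic(
    g_i: Sequence[int],
    g_j: Sequence[int],
    q: Mapping[int, float],
    w: SharingWeight = SharingWeight(),
) -> float:
    """S_ij for one pair at one marker (no missing alleles allowed here;
    pair-level masking is the caller's job)."""
    total = 0.0
    for a in g_i:
        if a not in q:
            raise KeyError(f"allele {a} absent from frequency table")
        for b in g_j:
            if b not in q:
                raise KeyError(f"allele {b} absent from frequency table")
            if a == b:
                total += w.f(q[a])
    return total / 4.0


def apm_observed(
    pairs: Sequence[RelativePair],
    genotypes: Mapping[str, Sequence[int]],
    q: Mapping[int, float],
    w: SharingWeight = SharingWeight(),
) -> tuple[float, int]:
    """Observed APM score at one marker: the sum of S_ij over affected
    pairs with complete genotypes.

    ``genotypes`` maps individual id to that marker's allele pair (0 or a
    missing entry = not typed).  Returns (score, number of contributing
    pairs); raises if no pair is informative.
    """
    score = 0.0
    n_inf = 0
    for pair in pairs:
        gi = genotypes.get(pair.id_a)
        gj = genotypes.get(pair.id_b)
        if gi is None or gj is None or MISSING in gi or MISSING in gj:
            continue
        score += sharing_statistic(gi, gj, q, w)
        n_inf += 1
    if n_inf == 0:
        raise ValueError("no informative pairs at this marker")
    return score, n_inf


class PairScorer:
    """Vectorised APM scoring of many markers over many gene-drop replicates.

    Built once per chromosome from the observed genotype array (shape
    (n_individuals, n_markers, 2), allele label 0 = missing), the affected
    pair list, and per-marker weight lookups; pairs with an incomplete
    observed genotype at a marker are excluded from that marker's score in
    the observed data and in every null replicate alike, so the null
    reflects the observed information pattern.
    """

    def __init__(
        self,
        obs_geno: np.ndarray,
        pair_idx: np.ndarray,
        weight_lookups: Sequence[np.ndarray],
    ):
        obs_geno = np.asarray(obs_geno)
        if obs_geno.ndim != 3 or obs_geno.shape[2] != 2:
            raise ValueError("obs_geno must have shape (n_ind, n_markers, 2)")
        self.obs_geno = obs_geno
        self.pair_idx = np.asarray(pair_idx, dtype=np.int64)
        self.weight_lookups = [np.asarray(w, dtype=float) for w in weight_lookups]
        n_markers = obs_geno.shape[1]
        if len(self.weight_lookups) != n_markers:
            raise ValueError("one weight lookup per marker required")
        ia, ib = self.pair_idx[:, 0], self.pair_idx[:, 1]
        typed = np.all(obs_geno != MISSING, axis=2)  # (N, M)
        self.informative = typed[ia] & typed[ib]  # (P, M)
        self.n_informative = self.informative.sum(axis=0)

    def score(self, geno: np.ndarray) -> np.ndarray:
        """Score every marker for a batch of genotype assignments.

        ``geno``: (n_reps, n_ind, n_markers, 2) allele labels.  Returns
        (n_reps, n_markers) APM scores.
        """
        geno = np.asarray(geno)
        n_reps, _, n_markers, _ = geno.shape
        out = np.zeros((n_reps, n_markers))
        ia, ib = self.pair_idx[:, 0], self.pair_idx[:, 1]
        for m in range(n_markers):
            mask = self.informative[:, m]
            if not mask.any():
                continue
            A = geno[:, ia[mask], m, :]  # (R, P', 2)
            B = geno[:, ib[mask], m, :]
            delta = A[:, :, :, None] == B[:, :, None, :]
            wa = self.weight_lookups[m][A]
            out[:, m] = 0.25 * (delta * wa[:, :, :, None]).sum(axis=(1, 2, 3))
        return out

    def observed(self) -> np.ndarray:
        """Observed APM score per marker (masked pairs excluded)."""
        return self.score(self.obs_geno[None])[0]


# ---------------------------------------------------------------------------
# null distributions and Z / p-values
# ---------------------------------------------------------------------------

def _check_nondegenerate(null: np.ndarray) -> None:
    if np.ptp(null) == 0:
        raise DegenerateNullError(
            "all null replicate scores are identical; cannot standardise "
            "(marker effectively monomorphic?)"
        )


def null_distribution(
    ped: Pedigree,
    pairs: Sequence[RelativePair],
    freqs: AlleleFrequencyTable,
    gmap: Optional[GeneticMap],
    marker: str,
    obs_geno_by_id: Mapping[str, Sequence[int]],
    n_reps: int = 500,
    mode: str = "unlinked",
    weight: SharingWeight = SharingWeight(),
    rng_seed: np.random.Generator | int = 0,
) -> np.ndarray:
    """Gene-drop null scores for one marker.

    ``mode="unlinked"`` drops the marker alone; ``mode="linked"`` drops the
    marker's whole chromosome (requires ``gmap``) and extracts this marker,
    so repeated calls share no replicates — the pipeline uses
    :class:`PairScorer` directly to share one linked ensemble per
    chromosome.  Observed missingness (0 alleles in ``obs_geno_by_id``) is
    masked in every replicate.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 null replicates")
    ids = ped.ids
    idx = {iid: k for k, iid in enumerate(ids)}
    if mode == "unlinked":
        markers = [marker]
        geno = drop_unlinked_batch(ped, freqs, markers, n_reps, rng_seed)
    elif mode == "linked":
        if gmap is None:
            raise ValueError("linked mode requires a genetic map")
        chrom = gmap.chrom_of(marker)
        markers = gmap.markers(chrom)
        labels = [freqs.alleles(m) for m in markers]
        probs = [freqs._probs[m] for m in markers]
        thetas = np.atleast_1d(haldane_theta(np.diff(gmap.positions(chrom))))
        geno = drop_linked_batch(ped, labels, probs, thetas, n_reps, rng_seed)
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    m_pos = markers.index(marker)
    obs = np.zeros((len(ids), len(markers), 2), dtype=np.int64)
    for iid, g in obs_geno_by_id.items():
        obs[idx[iid], m_pos, :] = g
    lookups = [freqs.weight_lookup(m, weight.form) for m in markers]
    scorer = PairScorer(
        obs, np.asarray([[idx[p.id_a], idx[p.id_b]] for p in pairs]), lookups
    )
    null = scorer.score(geno)[:, m_pos]
    _check_nondegenerate(null)
    return null


def z_and_pvalues(
    observed: float,
    null: Sequence[float],
    empirical: str = "plugin",
) -> tuple[float, float, float]:
    """Standardise an observed score against its Monte Carlo null.

    Z = (observed - mean(null)) / sd(null), signed so that excess sharing
    gives positive Z; asymptotic p is the upper-tail standard normal
    probability; empirical p is the proportion of null scores >= observed
    (``empirical="add_one"`` uses (k+1)/(n+1) to avoid zero p-values).
    """
    null = np.asarray(null, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null values")
    sd = null.std(ddof=1)
    if sd == 0:
        raise DegenerateNullError("null distribution has zero variance")
    z = (observed - null.mean()) / sd
    p_asym = float(sps.norm.sf(z))
    k = int(np.sum(null >= observed))
    if empirical == "plugin":
        p_emp = k / null.size
    elif empirical == "add_one":
        p_emp = (k + 1) / (null.size + 1)
    else:
        raise ValueError(f"unknown empirical p convention {empirical!r}")
    return float(z), p_asym, float(p_emp)


# ---------------------------------------------------------------------------
# multipoint
# ---------------------------------------------------------------------------

def multipoint_window(
    obs_scores: np.ndarray,
    null_scores: np.ndarray,
    window_idx: Sequence[int],
    empirical: str = "plugin",
) -> dict:
    """Multipoint statistic for a window of adjacent markers: the plain sum
    of per-marker APM scores, with the null summed identically over the
    same linked replicates (so inter-marker dependence is in the null).

    ``obs_scores``: (M,) observed per-marker scores on one chromosome;
    ``null_scores``: (R, M) from linked gene drops of that chromosome.
    """
    window_idx = list(window_idx)
    if not window_idx:
        raise ValueError("empty multipoint window")
    obs = float(np.sum(np.asarray(obs_scores)[window_idx]))
    null = np.asarray(null_scores)[:, window_idx].sum(axis=1)
    _check_nondegenerate(null)
    z, p_asym, p_emp = z_and_pvalues(obs, null, empirical=empirical)
    return {
        "observed": obs,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "Z": z,
        "p_asymptotic": p_asym,
        "p_empirical": p_emp,
        "null_scores": null,
    }


def grid_weights(d_left_cm: float, d_right_cm: float) -> tuple[float, float]:
    """Flanking-marker weights for a grid position between two markers.

    Each marker is weighted inversely by its recombination probability with
    the grid position: w_L proportional to 1/theta(d_L), normalised to sum
    to one.  At (or numerically on top of) a marker the weight collapses to
    that marker.
    """
    eps = 1e-12
    if d_left_cm < 0 or d_right_cm < 0:
        raise ValueError("distances cannot be negative")
    if d_left_cm <= eps and d_right_cm <= eps:
        return 0.5, 0.5
    if d_left_cm <= eps:
        return 1.0, 0.0
    if d_right_cm <= eps:
        return 0.0, 1.0
    inv_l = 1.0 / haldane_theta(d_left_cm)
    inv_r = 1.0 / haldane_theta(d_right_cm)
    w_l = inv_l / (inv_l + inv_r)
    return w_l, 1.0 - w_l


def grid_multipoint(
    obs_scores: np.ndarray,
    null_scores: np.ndarray,
    positions_cm: np.ndarray,
    step_cm: float = 1.0,
    empirical: str = "plugin",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Multipoint scores on a cM grid between adjacent markers.

    For a grid position x between flanking markers L and R the observed
    score is w_L * score(L) + w_R * score(R) with recombination-inverse
    weights (:func:`grid_weights`); the same linear combination is applied
    to every linked null replicate before standardisation.  Returns the
    per-grid-point results, the grid positions, and the (R, n_grid) null
    score matrix for downstream genome-wide adjustment.
    """
    obs_scores = np.asarray(obs_scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    positions = np.asarray(positions_cm, dtype=float)
    n_markers = positions.size
    if n_markers < 1:
        raise ValueError("no markers on chromosome")
    if n_markers == 1:
        grid = positions.copy()
    else:
        grid = np.arange(positions[0], positions[-1] + 1e-9, step_cm)
        if grid[-1] < positions[-1] - 1e-9:
            grid = np.append(grid, positions[-1])
    rows = []
    null_grid = np.zeros((null_scores.shape[0], grid.size))
    for k, x in enumerate(grid):
        right = int(np.searchsorted(positions, x + 1e-9))
        left = max(right - 1, 0)
        right = min(right, n_markers - 1)
        w_l, w_r = (1.0, 0.0) if left == right else grid_weights(
            x - positions[left], positions[right] - x
        )
        obs = w_l * obs_scores[left] + w_r * obs_scores[right]
        null = w_l * null_scores[:, left] + w_r * null_scores[:, right]
        null_grid[:, k] = null
        z, p_asym, p_emp = z_and_pvalues(obs, null, empirical=empirical)
        rows.append(
            {
                "position_cM": float(x),
                "observed": float(obs),
                "null_mean": float(null.mean()),
                "null_sd": float(null.std(ddof=1)),
                "Z": z,
                "p_asymptotic": p_asym,
                "p_empirical": p_emp,
            }
        )
    return pd.DataFrame(rows), grid, null_grid


# ---------------------------------------------------------------------------
# genome-wide adjustment and meta-analysis
# ---------------------------------------------------------------------------

def genomewide_adjust(
    observed_z: np.ndarray,
    null_scores: np.ndarray,
    standardize: str = "pooled",
) -> np.ndarray:
    """Experiment-wise (adjusted) p-values from the genome-wide null.

    Each null replicate is turned into a genome-wide Z curve by
    standardising its score at every locus; the adjusted p at a locus is the
    proportion of replicates whose genome-wide maximum Z reaches the
    observed Z there (ties count against the observed value).  ``pooled``
    standardises each replicate with all replicates' moments, which makes
    the single-locus case collapse exactly to the empirical p;
    ``leave_one_out`` excludes the replicate's own score from the moments.
    """
    observed_z = np.asarray(observed_z, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    n_loci, n_reps = null_scores.shape
    if observed_z.shape != (n_loci,):
        raise ValueError("one observed Z per locus required")
    if n_reps < 20:
        warnings.warn(
            f"only {n_reps} null replicates; adjusted p-value tail is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    m = null_scores.mean(axis=1, keepdims=True)
    sd = null_scores.std(axis=1, ddof=1, keepdims=True)
    ok = (sd > 0).ravel()
    if not ok.any():
        raise DegenerateNullError("all loci have degenerate nulls")
    if standardize == "pooled":
        z_null = np.where(sd > 0, (null_scores - m) / np.where(sd > 0, sd, 1.0), -np.inf)
    elif standardize == "leave_one_out":
        s = null_scores.sum(axis=1, keepdims=True)
        ss = ((null_scores - m) ** 2).sum(axis=1, keepdims=True)
        m_loo = (s - null_scores) / (n_reps - 1)
        ss_loo = ss - (n_reps / (n_reps - 1)) * (null_scores - m) ** 2
        var_loo = np.maximum(ss_loo, 0.0) / (n_reps - 2)
        sd_loo = np.sqrt(var_loo)
        z_null = np.where(sd_loo > 0, (null_scores - m_loo) / np.where(sd_loo > 0, sd_loo, 1.0), -np.inf)
    else:
        raise ValueError(f"unknown standardisation {standardize!r}")
    max_z = z_null[ok].max(axis=0)  # (n_reps,)
    return np.asarray([(max_z >= z).mean() for z in observed_z])


def meta_combine(
    studies: Sequence[MetaInput],
    grid_cm: Optional[np.ndarray] = None,
    step_cm: float = 1.0,
) -> pd.DataFrame:
    """Combine per-study Z curves by the weighted mean Z-score rule:

        Z_meta = sum_k w_k Z_k / sqrt(sum_k w_k^2)

    (unweighted default w_k = 1, so two studies give (Z1+Z2)/sqrt(2)).
    Studies are linearly interpolated onto a shared cM grid restricted to
    the overlap of their maps; p is the upper-tail normal probability.
    """
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    lo = max(s.positions_cm[0] for s in studies)
    hi = min(s.positions_cm[-1] for s in studies)
    if hi < lo:
        raise ValueError("study maps do not overlap")
    if grid_cm is None:
        grid_cm = np.arange(lo, hi + 1e-9, step_cm)
    else:
        grid_cm = np.asarray(grid_cm, dtype=float)
        if np.any(grid_cm < lo - 1e-9) or np.any(grid_cm > hi + 1e-9):
            raise ValueError("grid extends beyond the studies' shared map range")
    num = np.zeros_like(grid_cm, dtype=float)
    wsq = 0.0
    for s in studies:
        zk = np.interp(grid_cm, s.positions_cm, s.z)
        num += s.weight * zk
        wsq += s.weight**2
    z_meta = num / np.sqrt(wsq)
    return pd.DataFrame(
        {
            "position_cM": grid_cm,
            "Z_meta": z_meta,
            "p_meta": sps.norm.sf(z_meta),
        }
    )
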