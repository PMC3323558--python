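"""Mendelian gene-dropping simulation.

Gene dropping generates the null distribution for the linkage statistics:
founder alleles are assigned at random in proportion to their population
frequencies, then transmitted by descent through the pedigree.  For linked
markers, whole chromosomes are transmitted with between-marker recombination
probabilities given by Haldane's mapping function (no interference); an
unlinked marker is simply the special case of a recombination fraction of
one half with every neighbour.

All drops are vectorised across replicates: one call simulates the whole
pedigree for ``n_reps`` replicates at once, which is what makes 500-replicate
nulls at every marker of a genome scan affordable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GeneticMap",
    "AlleleFrequencyTable",
    "DropReplicate",
    "haldane_theta",
    "drop_unlinked",
    "drop_unlinked_batch",
    "drop_linked_chromosome",
    "drop_linked_batch",
    "estimate_ibd",
]

MISSING = 0  # allele code for a missing call; real alleles are labelled 1..K


def haldane_theta(d_cm):
    """Recombination fraction from map distance (cM) under Haldane's map
    function: theta = (1 - exp(-2 d)) / 2 with d in Morgans.

    Accepts scalars or arrays; raises on negative distances.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance cannot be negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cm) else theta


class GeneticMap:
    """Per-chromosome ordered marker positions in centimorgans.

    Positions must be non-decreasing within a chromosome and marker names
    unique genome-wide.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "marker", "cM"}
        if not required <= set(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        if table["marker"].duplicated().any():
            dups = table["marker"][table["marker"].duplicated()].tolist()
            raise ValueError(f"duplicate marker names in map: {dups}")
        self._chroms: dict[str, tuple[list[str], np.ndarray]] = {}
        self._marker_chrom: dict[str, str] = {}
        for chrom, grp in table.groupby("chrom", sort=False):
            pos = grp["cM"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions on chromosome {chrom} not sorted")
            names = grp["marker"].tolist()
            self._chroms[str(chrom)] = (names, pos)
            for name in names:
                self._marker_chrom[name] = str(chrom)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chroms)

    def markers(self, chrom: str) -> list[str]:
        return list(self._chroms[str(chrom)][0])

    def positions(self, chrom: str) -> np.ndarray:
        return self._chroms[str(chrom)][1].copy()

    def chrom_of(self, marker: str) -> str:
        return self._marker_chrom[marker]

    def position_of(self, marker: str) -> float:
        chrom = self._marker_chrom[marker]
        names, pos = self._chroms[chrom]
        return float(pos[names.index(marker)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (names, pos) in self._chroms.items():
            for n, p in zip(names, pos):
                rows.append({"chrom": chrom, "marker": n, "cM": p})
        return pd.DataFrame(rows)


class AlleleFrequencyTable:
    """Population allele frequencies per marker.

    ``freqs`` maps marker name to a mapping allele label (positive int) ->
    frequency.  Each marker needs at least two alleles with positive
    frequencies summing to 1 within 1e-6.
    """

    def __init__(self, freqs: Mapping[str, Mapping[int, float]]):
        self._labels: dict[str, np.ndarray] = {}
        self._probs: dict[str, np.ndarray] = {}
        for marker, qmap in freqs.items():
            labels = np.asarray(sorted(qmap), dtype=np.int64)
            probs = np.asarray([qmap[a] for a in labels], dtype=float)
            if labels.size < 2:
                raise ValueError(f"marker {marker!r} needs >= 2 alleles")
            if np.any(labels <= 0):
                raise ValueError(f"marker {marker!r} has non-positive allele labels")
            if np.any(probs <= 0):
                raise ValueError(f"marker {marker!r} has non-positive frequencies")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"frequencies for marker {marker!r} sum to {probs.sum():.8f}, not 1"
                )
            self._labels[marker] = labels
            self._probs[marker] = probs / probs.sum()

    def __contains__(self, marker: str) -> bool:
        return marker in self._labels

    @property
    def markers(self) -> list[str]:
        return list(self._labels)

    def alleles(self, marker: str) -> np.ndarray:
        return self._labels[marker].copy()

    def frequency(self, marker: str, allele: int) -> float:
        labels = self._labels[marker]
        idx = np.searchsorted(labels, allele)
        if idx >= labels.size or labels[idx] != allele:
            raise KeyError(f"allele {allele} absent from frequency table for {marker!r}")
        return float(self._probs[marker][idx])

    def weight_lookup(self, marker: str, form: str) -> np.ndarray:
        """Array ``w`` with ``w[allele_label] = f(q(allele))`` for fast
        vectorised scoring; index 0 (missing) is 0."""
        labels = self._labels[marker]
        q = self._probs[marker]
        if form == "constant":
            vals = np.ones_like(q)
        elif form == "inverse_sqrt":
            vals = 1.0 / np.sqrt(q)
        elif form == "inverse":
            vals = 1.0 / q
        else:
            raise ValueError(f"unknown sharing-weight form {form!r}")
        out = np.zeros(int(labels.max()) + 1)
        out[labels] = vals
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for marker in self._labels:
            for a, p in zip(self._labels[marker], self._probs[marker]):
                rows.append({"marker": marker, "allele": int(a), "frequency": float(p)})
        return pd.DataFrame(rows)


class DropReplicate:
    """One simulated genome-wide (or single-marker) genotype assignment.

    Genotypes are ordered allele pairs (paternal, maternal) indexed by
    (individual id, marker name).
    """

    def __init__(self, ids: Sequence[str], markers: Sequence[str], geno: np.ndarray):
        geno = np.asarray(geno)
        if geno.shape != (len(ids), len(markers), 2):
            raise ValueError("genotype array must have shape (n_ids, n_markers, 2)")
        self.ids = list(ids)
        self.markers = list(markers)
        self.geno = geno
        self._idx = {iid: k for k, iid in enumerate(self.ids)}
        self._midx = {m: k for k, m in enumerate(self.markers)}

    def genotype(self, iid: str, marker: str) -> tuple[int, int]:
        g = self.geno[self._idx[iid], self._midx[marker]]
        return int(g[0]), int(g[1])

    def __getitem__(self, key: tuple[str, str]) -> tuple[int, int]:
        return self.genotype(*key)


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------

def _ped_arrays(ped: Pedigree) -> tuple[dict[str, int], np.ndarray, list[tuple[int, int, int]]]:
    """Index map, founder indices, and (child, father, mother) triples in
    topological order."""
    ids = ped.ids
    idx = {iid: k for k, iid in enumerate(ids)}
    founders = np.asarray([idx[i] for i in ped.founders], dtype=np.int64)
    triples = []
    for iid in ids:
        ind = ped[iid]
        if not ind.is_founder:
            triples.append((idx[iid], idx[ind.father_id], idx[ind.mother_id]))
    return idx, founders, triples


def drop_linked_batch(
    ped: Pedigree,
    allele_labels: Sequence[np.ndarray],
    allele_probs: Sequence[np.ndarray],
    thetas: np.ndarray,
    n_reps: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Drop a set of markers through the pedigree, ``n_reps`` times.

    ``thetas`` holds the recombination fraction between each adjacent pair
    of markers (length M-1); 0.5 everywhere reproduces unlinked markers.
    Returns an int16 array of allele labels with shape
    ``(n_reps, n_individuals, n_markers, 2)`` where the last axis is
    (paternal, maternal) and individuals follow ``ped.ids`` order.
    """
    rng = np.random.default_rng(rng)
    n_markers = len(allele_labels)
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (max(n_markers - 1, 0),):
        raise ValueError("need one recombination fraction per adjacent marker pair")
    _, founders, triples = _ped_arrays(ped)
    n_ind = len(ped)
    geno = np.zeros((n_reps, n_ind, n_markers, 2), dtype=np.int16)

    for m in range(n_markers):
        cum = np.cumsum(allele_probs[m])
        draws = np.searchsorted(cum, rng.random((n_reps, founders.size, 2)))
        geno[:, founders, m, :] = allele_labels[m][draws].astype(np.int16)

    for child, father, mother in triples:
        for parent, slot in ((father, 0), (mother, 1)):
            start = rng.integers(0, 2, size=n_reps)
            if n_markers > 1:
                switches = rng.random((n_reps, n_markers - 1)) < thetas
                src = (start[:, None] + np.concatenate(
                    [np.zeros((n_reps, 1), dtype=np.int64),
                     np.cumsum(switches, axis=1)], axis=1)) % 2
            else:
                src = start[:, None].astype(np.int64)
            gamete = np.take_along_axis(
                geno[:, parent], src[:, :, None], axis=2
            )[:, :, 0]
            geno[:, child, :, slot] = gamete
    return geno


def drop_unlinked_batch(
    ped: Pedigree,
    freqs: AlleleFrequencyTable,
    markers: Sequence[str],
    n_reps: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Drop unlinked markers jointly (mutually independent transmissions).

    Equivalent to independent single-marker drops: unlinked loci recombine
    with probability one half.
    """
    labels = [freqs.alleles(m) for m in markers]
    probs = [freqs._probs[m] for m in markers]
    thetas = np.full(max(len(markers) - 1, 0), 0.5)
    return drop_linked_batch(ped, labels, probs, thetas, n_reps, rng)


def drop_unlinked(
    ped: Pedigree,
    freqs: AlleleFrequencyTable,
    marker: str,
    rng_seed: np.random.Generator | int,
) -> DropReplicate:
    """One gene-drop replicate of a single unlinked marker."""
    if marker not in freqs:
        raise KeyError(f"marker {marker!r} not in allele-frequency table")
    geno = drop_unlinked_batch(ped, freqs, [marker], 1, rng_seed)
    return DropReplicate(ped.ids, [marker], geno[0])


def drop_linked_chromosome(
    ped: Pedigree,
    freqs: AlleleFrequencyTable,
    gmap: GeneticMap,
    chrom: str,
    rng_seed: np.random.Generator | int,
) -> DropReplicate:
    """One gene-drop replicate of all markers on a chromosome, with Haldane
    recombination between adjacent markers and founder haplotypes drawn at
    linkage equilibrium."""
    if chrom not in gmap.chromosomes:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    markers = gmap.markers(chrom)
    for m in markers:
        if m not in freqs:
            raise KeyError(f"marker {m!r} on chromosome {chrom} missing from frequencies")
    labels = [freqs.alleles(m) for m in markers]
    probs = [freqs._probs[m] for m in markers]
    thetas = haldane_theta(np.diff(gmap.positions(chrom)))
    geno = drop_linked_batch(ped, labels, probs, np.atleast_1d(thetas), 1, rng_seed)
    return DropReplicate(ped.ids, markers, geno[0])


def estimate_ibd(
    ped: Pedigree,
    i: str,
    j: str,
    n_reps: int = 10_000,
    rng_seed: np.random.Generator | int = 0,
    return_se: bool = False,
):
    """Monte Carlo estimate of the expected proportion of alleles shared
    identical by descent between i and j.

    Drops one fully informative locus (every founder carries two unique
    alleles) ``n_reps`` times and averages the shared-allele proportion;
    for non-inbred pairs this converges to 2 phi(i, j).  Serves as the
    independent oracle for the kinship computation.  With ``return_se``
    the Monte Carlo standard error of the mean is returned alongside.
    """
    for iid in (i, j):
        if iid not in ped:
            raise KeyError(f"unknown individual id {iid!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    idx, founders, triples = _ped_arrays(ped)
    n_ind = len(ped)
    geno = np.zeros((n_reps, n_ind, 2), dtype=np.int32)
    unique = np.arange(1, 2 * founders.size + 1, dtype=np.int32).reshape(-1, 2)
    geno[:, founders, :] = unique[None, :, :]
    for child, father, mother in triples:
        for parent, slot in ((father, 0), (mother, 1)):
            pick = rng.integers(0, 2, size=n_reps)
            geno[:, child, slot] = geno[np.arange(n_reps), parent, pick]
    a = geno[:, idx[i], :]
    b = geno[:, idx[j], :]
    shared = (
        ((a[:, 0] == b[:, 0]) | (a[:, 0] == b[:, 1])).astype(np.int64)
        + ((a[:, 1] == b[:, 0]) | (a[:, 1] == b[:, 1])).astype(np.int64)
    )
    props = shared / 2.0
    est = float(props.mean())
    if return_se:
        se = float(props.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
        return est, se
    return est
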