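"""Study file formats, marker QC, and allele-frequency estimation.

Formats (all plain text, ``#``-prefixed comment headers allowed):

* LINKAGE-style ``.ped``: ``FID IID PAT MAT SEX PHENO`` plus two allele
  columns per marker in genetic-map order; allele code 0 = missing.
* PLINK-style ``.map``: ``chrom marker cM [bp]`` (physical positions are
  read and ignored).
* Allele-frequency TSV: ``marker  allele  frequency``.
* Phenotype TSV: ``id  sex  birth_year  death_year  attained_age``.
* Expected-lifespan TSV: ``sex  cohort_start  cohort_end  expected_lifespan``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genedrop import MISSING, AlleleFrequencyTable, GeneticMap
from .pedigree import Individual, Pedigree, validate_pedigree
from .phenotype import ExpectedLifespanTable

__all__ = [
    "GenotypePanel",
    "read_ped",
    "write_ped",
    "read_map",
    "write_map",
    "read_frequencies",
    "write_frequencies",
    "read_phenotypes",
    "write_phenotypes",
    "read_expected_lifespans",
    "write_expected_lifespans",
    "read_demographics_table",
    "filter_markers",
    "estimate_allele_frequencies",
]

_SEX_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


class GenotypePanel:
    """Individuals x markers table of unordered allele pairs.

    ``geno`` has shape (n_individuals, n_markers, 2) with integer allele
    labels; 0 means missing.  Genotypes are stored normalised (sorted allele
    pair) since phase is unknown in observed data.
    """

    def __init__(self, ids: Sequence[str], markers: Sequence[str], geno: np.ndarray):
        geno = np.asarray(geno, dtype=np.int32)
        if geno.shape != (len(ids), len(markers), 2):
            raise ValueError("genotype array shape must be (n_ids, n_markers, 2)")
        # normalise: a missing allele in a pair makes the whole call missing
        geno = np.sort(geno, axis=2)
        half = np.any(geno == MISSING, axis=2)
        geno[half] = MISSING
        self.ids = list(ids)
        self.markers = list(markers)
        self.geno = geno
        self._idx = {iid: k for k, iid in enumerate(self.ids)}
        self._midx = {m: k for k, m in enumerate(self.markers)}

    def __contains__(self, iid: str) -> bool:
        return iid in self._idx

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def genotype(self, iid: str, marker: str) -> tuple[int, int]:
        g = self.geno[self._idx[iid], self._midx[marker]]
        return int(g[0]), int(g[1])

    def genotypes_at(self, marker: str) -> dict[str, tuple[int, int]]:
        col = self.geno[:, self._midx[marker], :]
        return {iid: (int(a), int(b)) for iid, (a, b) in zip(self.ids, col)}

    def call_rate(self) -> pd.Series:
        """Fraction of individuals successfully typed, per marker."""
        typed = np.all(self.geno != MISSING, axis=2)
        return pd.Series(typed.mean(axis=0), index=self.markers, name="call_rate")

    def allele_counts(self) -> pd.Series:
        """Number of distinct observed alleles per marker."""
        out = {}
        for m in self.markers:
            col = self.geno[:, self._midx[m], :]
            out[m] = int(len(np.unique(col[col != MISSING])))
        return pd.Series(out, name="n_alleles")

    def subset_markers(self, markers: Iterable[str]) -> "GenotypePanel":
        markers = [m for m in markers if m in self._midx]
        cols = [self._midx[m] for m in markers]
        return GenotypePanel(self.ids, markers, self.geno[:, cols, :])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if line and not line.startswith("#"):
            lines.append((lineno, line))
    return lines


def read_map(path) -> GeneticMap:
    """PLINK-style map: chrom, marker, cM, optional bp."""
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
        try:
            rows.append({"chrom": parts[0], "marker": parts[1], "cM": float(parts[2])})
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad cM position {parts[2]!r}") from exc
    if not rows:
        raise ValueError(f"{path}: empty genetic map")
    return GeneticMap(pd.DataFrame(rows))


def write_map(gmap: GeneticMap, path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for _, row in gmap.to_frame().iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t{row['cM']:.4f}\n")


def read_ped(path, gmap: GeneticMap) -> tuple[Pedigree, GenotypePanel]:
    """LINKAGE-style .ped; marker columns follow the map's genome order."""
    markers = [m for c in gmap.chromosomes for m in gmap.markers(c)]
    n_cols = 6 + 2 * len(markers)
    inds: list[Individual] = []
    genos: list[np.ndarray] = []
    ids: list[str] = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} columns "
                f"(6 + 2 x {len(markers)} markers), got {len(parts)}"
            )
        _fid, iid, pat, mat, sex_code, _pheno = parts[:6]
        if iid in ids:
            raise ValueError(f"{path}:{lineno}: duplicate individual id {iid!r}")
        if sex_code not in _SEX_CODE:
            raise ValueError(f"{path}:{lineno}: bad sex code {sex_code!r}")
        inds.append(
            Individual(
                id=iid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=_SEX_CODE[sex_code],
            )
        )
        try:
            alleles = np.asarray(parts[6:], dtype=np.int32).reshape(-1, 2)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer allele code") from exc
        ids.append(iid)
        genos.append(alleles)
    if not inds:
        raise ValueError(f"{path}: empty pedigree file")
    ped = validate_pedigree(inds)
    panel = GenotypePanel(ids, markers, np.stack(genos))
    return ped, panel


def write_ped(
    ped: Pedigree,
    panel: GenotypePanel,
    path,
    affected: Optional[set[str]] = None,
    header: Optional[str] = None,
) -> None:
    affected = affected or set()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for ind in ped.members:
            pheno = "2" if ind.id in affected else "-9"
            cols = [
                "F0",
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_OUT[ind.sex],
                pheno,
            ]
            if ind.id in panel:
                g = panel.geno[panel._idx[ind.id]].ravel()
            else:
                g = np.zeros(2 * len(panel.markers), dtype=int)
            cols.extend(str(int(a)) for a in g)
            fh.write(" ".join(cols) + "\n")


def read_frequencies(path) -> AlleleFrequencyTable:
    freqs: dict[str, dict[int, float]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split()
        if parts[:1] == ["marker"]:
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected marker/allele/frequency")
        marker, allele, freq = parts
        try:
            freqs.setdefault(marker, {})[int(allele)] = float(freq)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad allele or frequency") from exc
    if not freqs:
        raise ValueError(f"{path}: empty frequency table")
    return AlleleFrequencyTable(freqs)


def write_frequencies(freqs: AlleleFrequencyTable, path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("marker\tallele\tfrequency\n")
        for _, row in freqs.to_frame().iterrows():
            fh.write(f"{row['marker']}\t{int(row['allele'])}\t{row['frequency']:.8f}\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    required = {"id", "sex", "birth_year", "death_year", "attained_age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df.set_index("id")


def write_phenotypes(df: pd.DataFrame, path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.2f")


def read_expected_lifespans(path) -> ExpectedLifespanTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ExpectedLifespanTable(df)


def write_expected_lifespans(
    table: ExpectedLifespanTable, path, header: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_demographics_table(path) -> pd.DataFrame:
    """Demographic summary fixture: per age band and sex, counts of affected
    individuals and of affected individuals with a typed relative."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"age_band", "affected_male", "affected_female",
                "typed_rel_male", "typed_rel_female"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: demographics table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# QC and allele-frequency estimation
# ---------------------------------------------------------------------------

def filter_markers(
    panel: GenotypePanel, threshold: float = 0.50
) -> tuple[pd.DataFrame, GenotypePanel]:
    """Keep markers successfully typed in at least ``threshold`` of subjects
    (closed threshold).  Returns the QC report and the filtered panel."""
    if not panel.markers:
        raise ValueError("empty genotype panel")
    rate = panel.call_rate()
    counts = panel.allele_counts()
    kept = rate >= threshold
    report = pd.DataFrame(
        {"call_rate": rate, "n_alleles": counts, "kept": kept}
    ).rename_axis("marker")
    return report, panel.subset_markers(report.index[kept])


def estimate_allele_frequencies(
    panel: GenotypePanel, control_ids: Iterable[str]
) -> AlleleFrequencyTable:
    """Allele frequencies by simple counting over control subjects.

    Per marker, q(g) is the count of allele g among non-missing control
    alleles divided by the total.  A marker with no typed control falls back
    to counting over all subjects (with a warning).  Alleles observed in the
    panel but absent among controls receive a pseudocount of one so the
    table always covers the panel.
    """
    controls = [c for c in control_ids if c in panel]
    if not controls:
        raise ValueError("no control subjects present in the genotype panel")
    ctl_rows = np.asarray([panel._idx[c] for c in controls])
    freqs: dict[str, dict[int, float]] = {}
    for m in panel.markers:
        col = panel.geno[:, panel._midx[m], :]
        ctl = col[ctl_rows].ravel()
        ctl = ctl[ctl != MISSING]
        if ctl.size == 0:
            warnings.warn(
                f"marker {m!r} has no typed control; falling back to all-subject counting",
                RuntimeWarning,
                stacklevel=2,
            )
            ctl = col.ravel()
            ctl = ctl[ctl != MISSING]
            if ctl.size == 0:
                continue  # entirely untyped marker: no frequencies estimable
        labels, counts = np.unique(ctl, return_counts=True)
        counts = counts.astype(float)
        observed_all = np.unique(col[col != MISSING])
        extra = np.setdiff1d(observed_all, labels)
        if extra.size:
            labels = np.concatenate([labels, extra])
            counts = np.concatenate([counts, np.ones(extra.size)])
        if labels.size < 2:
            continue  # monomorphic: unusable for sharing statistics
        total = counts.sum()
        freqs[m] = {int(a): c / total for a, c in zip(labels, counts)}
    if not freqs:
        raise ValueError("no marker yielded a usable allele-frequency estimate")
    return AlleleFrequencyTable(freqs)
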