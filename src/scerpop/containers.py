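"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as alt-allele dosage (0, 1, 2) with ``-1`` for missing,
one row per biallelic SNP site and one column per isolate.  Read-level
evidence travels as a long-format :class:`pandas.DataFrame` (one row per
isolate x site call) and ORF occupancy as a boolean isolates x ORFs frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every site-call table must carry
SITE_CALL_COLUMNS = [
    "isolate",
    "chrom",
    "pos",
    "depth",
    "ref_reads",
    "alt_reads",
    "genotype",
]

#: genotype labels used in site-call tables
GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"

GT_TO_DOSAGE = {GT_HOM_REF: 0, GT_HET: 1, GT_HOM_ALT: 2, GT_MISSING: MISSING}
DOSAGE_TO_GT = {v: k for k, v in GT_TO_DOSAGE.items()}


@dataclass
class GenotypeMatrix:
    """Sites x isolates diploid biallelic genotype matrix.

    Parameters
    ----------
    sites
        Site metadata with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; sorted by (chrom, pos), unique.
    isolates
        Isolate identifiers, one per matrix column.
    dosages
        ``int8`` array of shape (n_sites, n_isolates) with values in
        {0, 1, 2, -1}.
    """

    sites: pd.DataFrame
    isolates: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.isolates = list(self.isolates)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.isolates)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.isolates)} isolates"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")
        keys = list(zip(self.sites["chrom"], self.sites["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos) site entries")
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset (boolean mask or integer index), preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index],
            isolates=self.isolates,
            dosages=self.dosages[index],
        )

    def isolate_index(self, names) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.isolates)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown isolate {exc.args[0]!r}") from None

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, total called allele count)."""
        called = self.dosages != MISSING
        alt = np.where(called, self.dosages, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def maf(self) -> np.ndarray:
        """Minor allele frequency over non-missing alleles (NaN if none)."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.copy(), list(self.isolates), self.dosages.copy())


@dataclass
class PopulationMap:
    """Isolate -> lineage -> group -> population assignment."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ["isolate", "population", "group", "lineage"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["isolate"].duplicated().any():
            raise ValueError("duplicate isolate ids in sample sheet")
        # a lineage must belong to exactly one group, a group to one population
        for child, parent in [("lineage", "group"), ("group", "population")]:
            n = self.table.groupby(child)[parent].nunique()
            if (n > 1).any():
                bad = n[n > 1].index.tolist()
                raise ValueError(f"{child}(s) {bad} map to multiple {parent}s")
        self.table = self.table.reset_index(drop=True)

    @property
    def isolates(self) -> list[str]:
        return self.table["isolate"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    @property
    def lineages(self) -> list[str]:
        return sorted(self.table["lineage"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def members(self, level: str, name: str) -> list[str]:
        """Isolates assigned to ``name`` at ``level`` in {population, group, lineage}."""
        if level not in ("population", "group", "lineage"):
            raise ValueError(f"unknown level {level!r}")
        sel = self.table[self.table[level] == name]
        if sel.empty:
            raise ValueError(f"no isolates in {level} {name!r}")
        return sel["isolate"].tolist()

    def level_of(self, isolate: str, level: str) -> str:
        row = self.table[self.table["isolate"] == isolate]
        if row.empty:
            raise KeyError(f"unknown isolate {isolate!r}")
        return row[level].iloc[0]


def validate_site_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check site-call table invariants; returns the table unchanged."""
    missing = [c for c in SITE_CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"site-call table missing columns: {missing}")
    if (calls["depth"] < 0).any():
        raise ValueError("negative depth")
    if (calls["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    if ((calls["ref_reads"] + calls["alt_reads"]) > calls["depth"]).any():
        raise ValueError("ref_reads + alt_reads exceeds depth")
    bad = ~calls["genotype"].isin(GT_TO_DOSAGE)
    if bad.any():
        raise ValueError(f"unknown genotype labels: {sorted(calls.loc[bad, 'genotype'].unique())}")
    return calls


def new_presence_matrix(isolates, orf_ids, values=None) -> pd.DataFrame:
    """Boolean isolates x ORFs presence matrix (the pan-genome container)."""
    if values is None:
        values = np.zeros((len(isolates), len(orf_ids)), dtype=bool)
    pm = pd.DataFrame(np.asarray(values, dtype=bool), index=list(isolates), columns=list(orf_ids))
    if pm.columns.duplicated().any():
        raise ValueError("duplicate ORF ids")
    return pm
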