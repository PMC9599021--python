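"""Diploid SSR genotypes and per-locus diversity statistics.

A genotype table holds two allele sizes (bp) per genotype per locus, in the
common two-column-per-locus layout (``LOCUS.a1``/``LOCUS.a2``); a call is
either fully present or fully missing. From it the module computes the
standard marker-diversity statistics:

* allele frequencies (count-based, over 2 x n_typed observations),
* observed heterozygosity Ho -- fraction of typed individuals whose two
  alleles differ,
* expected heterozygosity (gene diversity) He = 1 - sum p_i^2,
* polymorphic information content
  PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

plus the across-locus summary (total alleles, mean alleles/locus, mean
He/Ho/PIC), by convention restricted to polymorphic loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSRGenotypeTable",
    "LocusStats",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "locus_stats",
    "summarize_loci",
]

_FREQ_TOL = 1e-8


class SSRGenotypeTable:
    """N genotypes x L loci of diploid allele-size calls.

    ``calls`` is an (N, L, 2) float array; missing calls are NaN in both
    slots. Allele sizes are positive integers (fragment lengths in bp),
    assumed pre-binned by the caller.
    """

    def __init__(
        self,
        genotypes: Sequence[str],
        loci: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(genotypes), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(genotypes)}, {len(loci)}, 2)"
            )
        half_missing = np.isnan(calls).sum(axis=2) == 1
        if half_missing.any():
            g, l = np.argwhere(half_missing)[0]
            raise ValueError(
                f"half-missing call for genotype {genotypes[g]!r} at locus "
                f"{loci[l]!r}: a call is either fully present or fully missing"
            )
        present = ~np.isnan(calls)
        vals = calls[present]
        if np.any(vals <= 0) or np.any(vals != np.round(vals)):
            raise ValueError("allele sizes must be positive integers (bp)")
        if len(set(genotypes)) != len(genotypes):
            raise ValueError("duplicate genotype labels")
        self.genotypes = list(map(str, genotypes))
        self.loci = list(map(str, loci))
        self.calls = calls

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SSRGenotypeTable({len(self.genotypes)} genotypes x "
            f"{len(self.loci)} loci)"
        )

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def locus_calls(self, locus: str) -> np.ndarray:
        """(N, 2) allele sizes at one locus, NaN rows = missing."""
        return self.calls[:, self.locus_index(locus), :]

    def typed_mask(self, locus: str) -> np.ndarray:
        return ~np.isnan(self.locus_calls(locus)[:, 0])

    def n_typed(self, locus: str) -> int:
        return int(self.typed_mask(locus).sum())

    def is_monomorphic(self, locus: str) -> bool:
        calls = self.locus_calls(locus)
        vals = calls[~np.isnan(calls)]
        if vals.size == 0:
            raise ValueError(f"locus {locus!r} has no typed calls")
        return np.unique(vals).size == 1

    def to_dataframe(self) -> pd.DataFrame:
        """Two-column-per-locus layout; missing encoded as 0."""
        data: dict[str, np.ndarray] = {}
        for j, locus in enumerate(self.loci):
            for k, suff in enumerate((".a1", ".a2")):
                col = self.calls[:, j, k]
                data[locus + suff] = np.where(np.isnan(col), 0, col).astype(int)
        return pd.DataFrame(data, index=pd.Index(self.genotypes, name="genotype"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SSRGenotypeTable":
        """Inverse of :meth:`to_dataframe`; 0/NaN entries mean missing."""
        loci: list[str] = []
        for col in df.columns:
            if col.endswith(".a1"):
                loci.append(col[:-3])
        for locus in loci:
            if f"{locus}.a2" not in df.columns:
                raise ValueError(f"locus {locus!r} lacks its .a2 column")
        calls = np.full((len(df), len(loci), 2), np.nan)
        for j, locus in enumerate(loci):
            for k, suff in enumerate((".a1", ".a2")):
                v = pd.to_numeric(df[locus + suff], errors="raise").to_numpy(dtype=float)
                v = np.where(v == 0, np.nan, v)
                calls[:, j, k] = v
        # a half-missing pair is malformed; report location via constructor
        return cls(list(map(str, df.index)), loci, calls)

    def subset(self, genotypes: Iterable[str]) -> "SSRGenotypeTable":
        keep = list(genotypes)
        idx = [self.genotypes.index(g) for g in keep]
        return SSRGenotypeTable(keep, self.loci, self.calls[idx])


@dataclass(frozen=True)
class LocusStats:
    locus: str
    n_alleles: int
    frequencies: dict[int, float]
    he: float
    ho: float
    pic: float
    n_typed: int


def allele_frequencies(table: SSRGenotypeTable, locus: str) -> dict[int, float]:
    """Count-based allele frequencies over the 2 x n_typed observed alleles."""
    calls = table.locus_calls(locus)
    alleles = calls[~np.isnan(calls)].astype(int)
    if alleles.size == 0:
        raise ValueError(f"locus {locus!r} has no typed calls")
    sizes, counts = np.unique(alleles, return_counts=True)
    return {int(s): float(c) / alleles.size for s, c in zip(sizes, counts)}


def observed_heterozygosity(table: SSRGenotypeTable, locus: str) -> float:
    """Fraction of typed genotypes carrying two different alleles."""
    calls = table.locus_calls(locus)
    typed = calls[~np.isnan(calls[:, 0])]
    if typed.size == 0:
        raise ValueError(f"locus {locus!r} has no typed calls")
    return float(np.mean(typed[:, 0] != typed[:, 1]))


def _check_simplex(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(freqs), dtype=float)
    if p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return p


def expected_heterozygosity(
    freqs: Mapping[int, float] | Sequence[float],
    *,
    bias_corrected: bool = False,
    n_typed: int | None = None,
) -> float:
    """Gene diversity He = 1 - sum p_i^2.

    With ``bias_corrected=True`` applies the small-sample factor
    2n/(2n-1) (``n_typed`` genotypes), giving the unbiased estimator.
    """
    p = _check_simplex(freqs.values() if isinstance(freqs, Mapping) else freqs)
    he = 1.0 - float(np.sum(p**2))
    if bias_corrected:
        if n_typed is None or n_typed < 1:
            raise ValueError("bias correction needs n_typed >= 1")
        n2 = 2 * n_typed
        if n2 < 2:
            raise ValueError("bias correction needs at least one diploid genotype")
        he *= n2 / (n2 - 1)
    return he


def pic(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Polymorphic information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2; always <= He, with the
    gap accounting for matings that cannot be distinguished at the marker.
    """
    p = _check_simplex(freqs.values() if isinstance(freqs, Mapping) else freqs)
    s2 = float(np.sum(p**2))
    sq = p**2
    cross = float(np.sum(np.outer(sq, sq)) - np.sum(sq**2))  # 2 * sum_{i<j}
    return 1.0 - s2 - cross


def locus_stats(
    table: SSRGenotypeTable, locus: str, *, bias_corrected: bool = False
) -> LocusStats:
    """All per-locus statistics in one pass."""
    freqs = allele_frequencies(table, locus)
    n_typed = table.n_typed(locus)
    return LocusStats(
        locus=locus,
        n_alleles=len(freqs),
        frequencies=freqs,
        he=expected_heterozygosity(
            freqs, bias_corrected=bias_corrected, n_typed=n_typed
        ),
        ho=observed_heterozygosity(table, locus),
        pic=pic(freqs),
        n_typed=n_typed,
    )


def summarize_loci(
    stats: Sequence[LocusStats], *, polymorphic_only: bool = True
) -> dict[str, float]:
    """Study-level summary across loci.

    Monomorphic loci are excluded by default, matching the convention of
    reporting marker statistics for polymorphic loci only.
    """
    if not stats:
        raise ValueError("no loci to summarize")
    use = [s for s in stats if s.n_alleles > 1] if polymorphic_only else list(stats)
    if not use:
        raise ValueError("no polymorphic loci to summarize")
    return {
        "n_loci": float(len(use)),
        "total_alleles": float(sum(s.n_alleles for s in use)),
        "mean_alleles": float(np.mean([s.n_alleles for s in use])),
        "mean_he": float(np.mean([s.he for s in use])),
        "mean_ho": float(np.mean([s.ho for s in use])),
        "mean_pic": float(np.mean([s.pic for s in use])),
    }
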