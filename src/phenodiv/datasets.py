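"""Packaged reference tables.

Two small CSV fixtures ship with the package: the published genotype-level
assay means (+/- SE, n = 3) for the 25-genotype berry screen, and the
published per-locus SSR diversity statistics for the 7 polymorphic loci
scored on the 24 diploid red raspberry genotypes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ssr import LocusStats

__all__ = ["load_berry_means", "load_locus_reference", "locus_reference_stats"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("phenodiv.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def load_berry_means() -> pd.DataFrame:
    """Genotype means and SEs for TPC, TFC, TAC, FRAP and ABTS (berries)."""
    return _read("berry_means.csv")


def load_locus_reference() -> pd.DataFrame:
    """Per-locus allele counts and He/Ho/PIC for the polymorphic SSR panel."""
    return _read("locus_stats.csv")


def locus_reference_stats() -> list[LocusStats]:
    """The locus reference as :class:`~phenodiv.ssr.LocusStats` records.

    Allele frequencies were not published, so ``frequencies`` is empty and
    ``n_typed`` reflects the 24 genotypes scored.
    """
    df = load_locus_reference()
    return [
        LocusStats(
            locus=row.locus,
            n_alleles=int(row.n_alleles),
            frequencies={},
            he=float(row.He),
            ho=float(row.Ho),
            pic=float(row.PIC),
            n_typed=24,
        )
        for row in df.itertuples()
    ]
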