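"""Synthetic study generator.

Emulates the design of a 25-genotype berry germplasm screen: three replicate
extractions per genotype with roughly proportional (CV-scaled) replicate
noise around genotype-level assay truths, raw absorbance records obtained by
inverting the quantification chain through the configured calibration curves
(so the quantification module can be exercised end to end), and diploid SSR
genotypes drawn under Hardy-Weinberg equilibrium at multiallelic loci.

An optional association couples the dosage of one designated allele to a
shift of the TPC and FRAP truths, giving the genetic and biochemical
distance structures a common cause so the Mantel machinery has something to
detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import Assay, CalibrationCurve, ExtractContext
from .datasets import load_berry_means
from .ssr import SSRGenotypeTable

__all__ = [
    "LocusSpec",
    "AssociationSpec",
    "SimulationConfig",
    "DEFAULT_CURVES",
    "DEFAULT_DILUTIONS",
    "DEFAULT_LOCI",
    "simulate_assays",
    "simulate_genotypes",
    "simulate_study",
]

#: default linear calibration curves (response = slope * conc + intercept).
#: TPC/TFC respond in absorbance vs ug/mL; FRAP in absorbance vs mM Trolox;
#: ABTS in %inhibition vs mM Trolox. TAC is absolute and needs no curve.
DEFAULT_CURVES: dict[Assay, CalibrationCurve] = {
    Assay.TPC: CalibrationCurve("gallic acid", 0.005, 0.0, (10.0, 300.0)),
    Assay.TFC: CalibrationCurve("rutin", 0.0008, 0.0, (50.0, 1000.0)),
    Assay.FRAP: CalibrationCurve("Trolox", 0.9, 0.02, (0.05, 1.0)),
    Assay.ABTS: CalibrationCurve("Trolox", 80.0, 0.0, (0.05, 1.0)),
}

#: default per-assay dilution factors, chosen so the published value ranges
#: land inside the calibration ranges (and, for ABTS, inside the 20-80 %
#: inhibition window)
DEFAULT_DILUTIONS: dict[Assay, float] = {
    Assay.TPC: 2.0,
    Assay.TFC: 1.0,
    Assay.TAC: 10.0,
    Assay.FRAP: 10.0,
    Assay.ABTS: 10.0,
}

_ABTS_BLANK = 0.70
# fixed background readings for the four-cuvette pH-differential protocol
_TAC_BACKGROUND = {"A700_pH1.0": 0.02, "A510_pH4.5": 0.05, "A700_pH4.5": 0.01}


@dataclass(frozen=True)
class LocusSpec:
    """One SSR locus: allele fragment sizes (bp) and their frequencies."""

    name: str
    sizes: tuple[int, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.freqs):
            raise ValueError(f"locus {self.name!r}: sizes/freqs length mismatch")
        p = np.asarray(self.freqs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"locus {self.name!r}: frequencies must form a simplex")
        if len(set(self.sizes)) != len(self.sizes):
            raise ValueError(f"locus {self.name!r}: duplicate allele sizes")


#: default 7-locus panel mirroring the allele counts (2,3,2,2,3,7,2) and the
#: skewed-to-diverse He profile of the study's polymorphic loci. FaFS01 is
#: the designated association locus; its two alleles are separated by a wide
#: indel-like gap so the allele-size distance metric can see it.
DEFAULT_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("RcFH01", (236, 238), (0.94, 0.06)),
    LocusSpec("FaFH01", (201, 204, 207), (0.90, 0.06, 0.04)),
    LocusSpec("FaFS01", (220, 244), (0.73, 0.27)),
    LocusSpec("RiAS01", (302, 306), (0.895, 0.105)),
    LocusSpec("RhUF01", (274, 277, 280), (0.915, 0.05, 0.035)),
    LocusSpec("RiMY01", (210, 214, 218, 222, 226, 230, 234), (0.30, 0.20, 0.15, 0.12, 0.10, 0.08, 0.05)),
    LocusSpec("RiG001", (330, 334), (0.915, 0.085)),
)


@dataclass(frozen=True)
class AssociationSpec:
    """Deterministic dosage effect of one designated allele on assay truths.

    ``shifts`` maps assay -> additive shift per copy of allele ``allele_size``
    at ``locus``. Effect presets are expressed in units of the
    between-genotype standard deviation of each shifted assay.
    """

    locus: str = "FaFS01"
    allele_size: int = 220
    shifts: Mapping[Assay, float] = field(default_factory=dict)


def association_preset(
    strength: str, truth: pd.DataFrame, locus: str = "FaFS01", allele_size: int = 220
) -> AssociationSpec:
    """Named association strengths: shift per allele copy on TPC and FRAP.

    ``"none"`` -> 0 SD, ``"moderate"`` -> 1 SD, ``"strong"`` -> 2 SD of the
    between-genotype spread of each trait.
    """
    mult = {"none": 0.0, "moderate": 1.0, "strong": 2.0}[strength]
    shifts = {
        a: mult * float(truth[a.value].std(ddof=1)) for a in (Assay.TPC, Assay.FRAP)
    }
    return AssociationSpec(locus, allele_size, shifts)


def _default_truth(n: int) -> pd.DataFrame:
    means = load_berry_means().set_index("genotype")
    t = means[[a.value for a in Assay]]
    if n > len(t):
        raise ValueError(f"default truth table has only {len(t)} genotypes")
    return t.iloc[:n].copy()


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the real design: 25 genotypes x 3 replicates, replicate
    CV 8 % (the magnitude implied by the published SEs relative to their
    means), the published genotype means as assay truths, berries extracted
    5 g into 30 mL, and the 7-locus SSR panel above.
    """

    n_genotypes: int = 25
    n_replicates: int = 3
    truth: pd.DataFrame | None = None  # genotype x assay means
    replicate_cv: float = 0.08
    loci: tuple[LocusSpec, ...] = DEFAULT_LOCI
    association: AssociationSpec | None = None
    curves: Mapping[Assay, CalibrationCurve] = field(
        default_factory=lambda: dict(DEFAULT_CURVES)
    )
    dilutions: Mapping[Assay, float] = field(
        default_factory=lambda: dict(DEFAULT_DILUTIONS)
    )
    context: ExtractContext = field(default_factory=ExtractContext)
    dry_matter_range: tuple[float, float] = (0.108, 0.184)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 genotypes and >= 1 replicate")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be >= 0")
        if self.truth is None:
            self.truth = _default_truth(self.n_genotypes)
        if len(self.truth) != self.n_genotypes:
            raise ValueError("truth table size does not match n_genotypes")


def _absorbance_records(
    value: float, assay: Assay, cfg: SimulationConfig
) -> tuple[dict[str, float], float]:
    """Invert the quantification chain: final units -> raw readings."""
    ctx = cfg.context
    df = cfg.dilutions[assay]
    if assay in (Assay.TPC, Assay.TFC):
        conc_extract = value * ctx.sample_mass_g / 100.0 * 1000.0 / ctx.extract_volume_ml
        curve = cfg.curves[assay]
        a = curve.slope * (conc_extract / df) + curve.intercept
        return {"A": a}, df
    if assay is Assay.TAC:
        mg_per_l = value * ctx.sample_mass_g / 100.0 * 1000.0 / ctx.extract_volume_ml
        a = mg_per_l * 26_900.0 / (449.2 * 1000.0 * df)
        r = dict(_TAC_BACKGROUND)
        r["A510_pH1.0"] = (
            a + r["A700_pH1.0"] + (r["A510_pH4.5"] - r["A700_pH4.5"])
        )
        return r, df
    # FRAP / ABTS: umol TE/g -> mM Trolox in the measured dilution
    conc_mm = value * ctx.sample_mass_g / ctx.extract_volume_ml / df
    curve = cfg.curves[assay]
    resp = curve.slope * conc_mm + curve.intercept
    if assay is Assay.FRAP:
        return {"A": resp}, df
    return {"A_sample": _ABTS_BLANK * (1.0 - resp / 100.0), "A_blank": _ABTS_BLANK}, df


def simulate_assays(
    cfg: SimulationConfig,
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw replicate values and the raw absorbance records behind them.

    Returns ``(replicates, absorbance, metadata)``: a long replicate table
    (genotype, assay, replicate, value), a long absorbance table matching the
    quantification input layout, and per-genotype metadata (dry-matter
    fraction drawn uniformly from the configured range).

    Replicate values are Normal(truth, cv * truth) truncated at zero, so with
    ``replicate_cv=0`` the chain is exactly invertible.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = cfg.truth if truth is None else truth
    rep_rows: list[dict] = []
    abs_rows: list[dict] = []
    for genotype, row in truth.iterrows():
        for assay in Assay:
            mu = float(row[assay.value])
            sd = cfg.replicate_cv * mu
            for rep in range(1, cfg.n_replicates + 1):
                v = float(np.clip(rng.normal(mu, sd) if sd > 0 else mu, 0.0, None))
                rep_rows.append(
                    {
                        "genotype": genotype,
                        "assay": assay.value,
                        "replicate": rep,
                        "value": v,
                    }
                )
                readings, df = _absorbance_records(v, assay, cfg)
                for name, a in readings.items():
                    abs_rows.append(
                        {
                            "genotype": genotype,
                            "assay": assay.value,
                            "replicate": rep,
                            "reading_name": name,
                            "value": a,
                            "dilution_factor": df,
                        }
                    )
    lo, hi = cfg.dry_matter_range
    meta = pd.DataFrame(
        {
            "genotype": list(truth.index),
            "tissue": "berry",
            "sample_mass_g": cfg.context.sample_mass_g,
            "extract_volume_ml": cfg.context.extract_volume_ml,
            "dry_matter_fraction": rng.uniform(lo, hi, size=len(truth)),
        }
    )
    return pd.DataFrame(rep_rows), pd.DataFrame(abs_rows), meta


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SSRGenotypeTable, pd.DataFrame]:
    """Draw HWE diploid genotypes; returns the table and the shifted truths.

    Each genotype's two alleles per locus are drawn independently from the
    locus frequency vector (Hardy-Weinberg, no linkage). When an association
    is configured, carriers of the designated allele get their assay truths
    shifted by ``dose * shift`` before any downstream assay simulation.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    names = list(cfg.truth.index)[: cfg.n_genotypes]
    L = len(cfg.loci)
    calls = np.zeros((len(names), L, 2))
    for j, locus in enumerate(cfg.loci):
        sizes = np.asarray(locus.sizes, dtype=float)
        draws = rng.choice(len(sizes), size=(len(names), 2), p=np.asarray(locus.freqs))
        calls[:, j, :] = np.sort(sizes[draws], axis=1)
    table = SSRGenotypeTable(names, [l.name for l in cfg.loci], calls)
    truth = cfg.truth.loc[names].copy()
    if cfg.association is not None and cfg.association.shifts:
        a = cfg.association
        li = table.locus_index(a.locus)
        dose = (calls[:, li, :] == float(a.allele_size)).sum(axis=1)
        for assay, shift in a.shifts.items():
            truth[Assay(assay).value] = truth[Assay(assay).value] + shift * dose
    return table, truth


def simulate_study(
    cfg: SimulationConfig,
) -> dict:
    """Full synthetic study: genotypes, (possibly shifted) truths, assays."""
    rng = np.random.default_rng(cfg.seed)
    table, truth = simulate_genotypes(cfg, rng)
    replicates, absorbance, meta = simulate_assays(cfg, truth, rng)
    return {
        "genotypes": table,
        "truth": truth,
        "replicates": replicates,
        "absorbance": absorbance,
        "metadata": meta,
    }
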