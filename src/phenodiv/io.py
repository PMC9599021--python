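"""Table readers/writers and the pipeline orchestrator.

All tables are plain UTF-8 comma-separated files with a header row. The SSR
genotype table uses the common two-column-per-locus layout (``LOCUS.a1``,
``LOCUS.a2``; 0 or blank = missing) importable into GenAlEx-style tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .assays import (
    Assay,
    AssayRecord,
    CalibrationCurve,
    ExtractContext,
    QuantResult,
    fw_to_dw,
    quantify,
)
from .cluster import biochem_distance, cut_clusters, genetic_distance, mantel_test, upgma
from .group_stats import duncan_mrt, grand_mean, pearson_matrix, range_ratio
from .simulate import DEFAULT_CURVES
from .ssr import SSRGenotypeTable, locus_stats, summarize_loci

log = logging.getLogger("phenodiv")

ASSAY_ORDER = [a.value for a in Assay]


def read_genotype_table(path: str | Path) -> SSRGenotypeTable:
    """Read a two-column-per-locus SSR genotype CSV."""
    df = pd.read_csv(path, comment="#")
    if "genotype" not in df.columns:
        raise ValueError(f"{path}: expected a 'genotype' column")
    df = df.set_index("genotype")
    allele_cols = [c for c in df.columns if c.endswith((".a1", ".a2"))]
    odd = [c for c in df.columns if c not in allele_cols]
    if odd:
        raise ValueError(f"{path}: unrecognized columns {odd}")
    try:
        return SSRGenotypeTable.from_dataframe(df[allele_cols])
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_genotype_table(table: SSRGenotypeTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path)


def read_absorbance(path: str | Path) -> pd.DataFrame:
    """Long absorbance table: genotype, assay, replicate, reading_name, value, dilution_factor."""
    df = pd.read_csv(path, comment="#")
    required = {"genotype", "assay", "replicate", "reading_name", "value", "dilution_factor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_context(path: str | Path) -> dict[str, ExtractContext]:
    """Per-genotype extraction context table."""
    df = pd.read_csv(path, comment="#")
    out = {}
    for row in df.itertuples():
        out[str(row.genotype)] = ExtractContext(
            sample_mass_g=float(row.sample_mass_g),
            extract_volume_ml=float(row.extract_volume_ml),
            dry_matter_fraction=(
                float(row.dry_matter_fraction)
                if "dry_matter_fraction" in df.columns
                and pd.notna(row.dry_matter_fraction)
                else None
            ),
        )
    return out


def read_curves(path: str | Path) -> dict[Assay, CalibrationCurve]:
    """Calibration curves from YAML/JSON: per-assay slope/intercept/range."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    out: dict[Assay, CalibrationCurve] = {}
    for key, spec in raw.items():
        out[Assay(key)] = CalibrationCurve(
            standard_name=spec.get("standard_name", "standard"),
            slope=float(spec["slope"]),
            intercept=float(spec.get("intercept", 0.0)),
            concentration_range=tuple(spec["concentration_range"]),
            r_squared=float(spec.get("r_squared", 1.0)),
        )
    return out


def quantify_table(
    absorbance: pd.DataFrame,
    contexts: Mapping[str, ExtractContext],
    curves: Mapping[Assay, CalibrationCurve] | None = None,
    basis: str = "FW",
) -> pd.DataFrame:
    """Quantify a long absorbance table into assay units.

    Returns columns genotype, assay, replicate, value, units, basis, flags.
    """
    curves = dict(DEFAULT_CURVES) if curves is None else curves
    rows = []
    grouped = absorbance.groupby(["genotype", "assay", "replicate"], sort=False)
    for (genotype, assay_name, rep), sub in grouped:
        assay = Assay(assay_name)
        readings = dict(zip(sub["reading_name"], sub["value"].astype(float)))
        dfs = sub["dilution_factor"].astype(float).unique()
        if len(dfs) != 1:
            raise ValueError(
                f"inconsistent dilution factors for {genotype}/{assay_name}/rep{rep}"
            )
        record = AssayRecord(str(genotype), assay, int(rep), readings, float(dfs[0]))
        ctx = contexts[str(genotype)]
        res: QuantResult = quantify(record, ctx, curves.get(assay))
        if basis.upper() == "DW":
            res = fw_to_dw(res, ctx)
        rows.append(
            {
                "genotype": res.genotype,
                "assay": res.assay.value,
                "replicate": res.replicate,
                "value": res.value,
                "units": res.units,
                "basis": res.basis,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def replicates_to_means(replicates: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long replicate table to a genotype x assay mean table."""
    wide = replicates.pivot_table(
        index="genotype", columns="assay", values="value", aggfunc="mean", sort=False
    )
    return wide[[a for a in ASSAY_ORDER if a in wide.columns]]


def stats_report(
    means: pd.DataFrame,
    replicates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Correlations, fold ranges, grand means and (optionally) Duncan letters."""
    corr = pearson_matrix(means)
    report: dict = {
        "correlations": corr.round(3).to_dict(),
        "range_ratio": {
            a: round(range_ratio(means[a]), 1)
            for a in means.columns
            if (means[a] > 0).all()
        },
        "grand_mean": {a: round(grand_mean(means[a]), 1) for a in means.columns},
    }
    if replicates is not None:
        letters: dict[str, dict[str, str]] = {}
        for assay_name, sub in replicates.groupby("assay", sort=False):
            groups = [
                g["value"].to_numpy(dtype=float)
                for _, g in sub.groupby("genotype", sort=False)
            ]
            names = [str(n) for n, _ in sub.groupby("genotype", sort=False)]
            res = duncan_mrt(groups, alpha)
            letters[str(assay_name)] = dict(zip(names, res.letters))
        report["duncan_letters"] = letters
    return report


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    absorbance: str
    context: str
    genotypes: str
    curves: str | None = None
    basis: str = "FW"
    alpha: float = 0.05
    standardize: bool = True
    polymorphic_only: bool = True
    distance_method: str = "allele_size_euclidean"
    biochem_variables: tuple[str, ...] = ("TPC", "TFC", "TAC")
    n_clusters: int = 5
    permutations: int = 9999
    seed: int = 1
    outdir: str = "phenodiv_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """quantify -> stats -> ssr -> tree -> mantel, writing every artifact.

    Any stage failure aborts with the stage name attached. Returns the
    report dictionary (also written to ``report.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
    }
    stage = "quantify"
    try:
        absorbance = read_absorbance(cfg.absorbance)
        contexts = read_context(cfg.context)
        curves = read_curves(cfg.curves) if cfg.curves else None
        quantified = quantify_table(absorbance, contexts, curves, cfg.basis)
        quantified.to_csv(outdir / "quantified.csv", index=False)

        stage = "stats"
        means = replicates_to_means(quantified)
        means.to_csv(outdir / "means.csv")
        report["stats"] = stats_report(means, quantified, cfg.alpha)
        pd.DataFrame(report["stats"]["correlations"]).to_csv(outdir / "correlations.csv")

        stage = "ssr"
        table = read_genotype_table(cfg.genotypes)
        per_locus = [locus_stats(table, l) for l in table.loci]
        locus_df = pd.DataFrame(
            {
                "locus": [s.locus for s in per_locus],
                "n_alleles": [s.n_alleles for s in per_locus],
                "He": [round(s.he, 3) for s in per_locus],
                "Ho": [round(s.ho, 3) for s in per_locus],
                "PIC": [round(s.pic, 3) for s in per_locus],
                "n_typed": [s.n_typed for s in per_locus],
            }
        )
        summary = summarize_loci(per_locus, polymorphic_only=cfg.polymorphic_only)
        locus_df.to_csv(outdir / "locus_stats.csv", index=False)
        report["ssr_summary"] = summary

        stage = "tree"
        shared = [g for g in means.index if g in table.genotypes]
        d_gen = genetic_distance(table.subset(shared), cfg.distance_method)
        tree = upgma(d_gen)
        (outdir / "dendrogram.nwk").write_text(tree.to_newick(), encoding="utf-8")
        clusters = cut_clusters(tree, min(cfg.n_clusters, len(shared)))
        pd.Series(clusters, name="cluster").rename_axis("genotype").to_csv(
            outdir / "clusters.csv"
        )
        report["clusters"] = clusters

        stage = "mantel"
        d_bio = biochem_distance(
            means.loc[shared],
            [v for v in cfg.biochem_variables if v in means.columns],
            standardize=cfg.standardize,
        )
        mres = mantel_test(d_bio, d_gen, cfg.permutations, cfg.seed)
        report["mantel"] = {
            "r": mres.r,
            "p_value": mres.p_value,
            "n_permutations": mres.n_permutations,
            "seed": mres.seed,
        }
        (outdir / "mantel.json").write_text(
            json.dumps(report["mantel"], indent=2), encoding="utf-8"
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=str), encoding="utf-8"
    )
    log.info("pipeline complete: %s", outdir)
    return report
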