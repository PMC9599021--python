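"""Colorimetric assay quantification.

Converts raw spectrophotometer readings into the concentration units
conventional for berry phenolics work:

* TPC (Folin-Ciocalteau) -- mg gallic acid equivalents (GAE) / 100 g FW
* TFC (AlCl3 colorimetric) -- mg rutin equivalents (RE) / 100 g FW
* TAC (pH-differential) -- mg cyanidin-3-glucoside equivalents / 100 g FW
* FRAP, ABTS -- umol Trolox equivalents (TE) / g FW

TPC, TFC, FRAP and ABTS go through a linear calibration curve fitted to
standard solutions; TAC is absolute, via the cyanidin-3-glucoside molar
extinction coefficient. Fresh-weight results can be rebased to dry weight
through the tissue's dry-matter fraction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "Assay",
    "CalibrationCurve",
    "AssayRecord",
    "ExtractContext",
    "QuantResult",
    "fit_standard_curve",
    "curve_invert",
    "quantify",
    "quantify_folin_type",
    "quantify_tac",
    "quantify_abts",
    "quantify_frap",
    "fw_to_dw",
    "TAC_EXTINCTION",
    "TAC_MOLAR_MASS",
    "ABTS_BLANK_TARGET",
    "ABTS_BLANK_TOL",
]

#: molar extinction coefficient of cyanidin-3-glucoside (L mol^-1 cm^-1)
TAC_EXTINCTION = 26_900.0
#: molar mass of cyanidin-3-glucoside (g/mol)
TAC_MOLAR_MASS = 449.2
#: cuvette path length (cm); standard 1 cm cell
TAC_PATH_LENGTH = 1.0

#: working-solution absorbance the ABTS protocol targets at 734 nm
ABTS_BLANK_TARGET = 0.70
ABTS_BLANK_TOL = 0.02

#: inhibition window (%) within which ABTS readings are considered reliable
ABTS_INHIBITION_WINDOW = (20.0, 80.0)


class Assay(str, enum.Enum):
    TPC = "TPC"
    TFC = "TFC"
    TAC = "TAC"
    FRAP = "FRAP"
    ABTS = "ABTS"


FW_UNITS = {
    Assay.TPC: "mg GAE/100 g FW",
    Assay.TFC: "mg RE/100 g FW",
    Assay.TAC: "mg cyan-3-G/100 g FW",
    Assay.FRAP: "umol TE/g FW",
    Assay.ABTS: "umol TE/g FW",
}
DW_UNITS = {
    Assay.TPC: "mg GAE/g DW",
    Assay.TFC: "mg RE/g DW",
    Assay.TAC: "mg cyan-3-G/g DW",
    Assay.FRAP: "umol TE/g DW",
    Assay.ABTS: "umol TE/g DW",
}

#: reading names each assay requires in ``AssayRecord.readings``
REQUIRED_READINGS = {
    Assay.TPC: ("A",),
    Assay.TFC: ("A",),
    Assay.TAC: ("A510_pH1.0", "A700_pH1.0", "A510_pH4.5", "A700_pH4.5"),
    Assay.FRAP: ("A",),
    Assay.ABTS: ("A_sample", "A_blank"),
}


class ExtrapolationWarning(UserWarning):
    """Inverse prediction fell outside the calibration range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: absorbance (or %inhibition) = slope*conc + intercept."""

    standard_name: str
    slope: float
    intercept: float
    concentration_range: tuple[float, float]
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.concentration_range
        if not lo < hi:
            raise ValueError("concentration_range must satisfy low < high")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class AssayRecord:
    """One replicate measurement: raw readings plus the dilution applied."""

    genotype: str
    assay: Assay
    replicate: int
    readings: dict[str, float]
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        missing = [k for k in REQUIRED_READINGS[self.assay] if k not in self.readings]
        if missing:
            raise ValueError(
                f"{self.assay.value} record for {self.genotype!r} lacks readings: {missing}"
            )
        for name, v in self.readings.items():
            if v < 0:
                raise ValueError(f"negative absorbance {name}={v}")


@dataclass(frozen=True)
class ExtractContext:
    """Extraction geometry: how much tissue went into how much solvent."""

    sample_mass_g: float = 5.0
    extract_volume_ml: float = 30.0
    dry_matter_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0 or self.extract_volume_ml <= 0:
            raise ValueError("sample mass and extract volume must be positive")
        if self.dry_matter_fraction is not None and not (
            0.0 < self.dry_matter_fraction < 1.0
        ):
            raise ValueError("dry_matter_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class QuantResult:
    genotype: str
    assay: Assay
    replicate: int
    value: float
    units: str
    basis: str = "FW"
    flags: tuple[str, ...] = field(default_factory=tuple)


def fit_standard_curve(
    points: Sequence[tuple[float, float]], standard_name: str = "standard"
) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, absorbance) pairs.

    At least three points are required and the concentrations must vary;
    ``r_squared`` is reported so poor curves can be rejected by the caller.
    """
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 standard points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    absb = np.asarray([p[1] for p in points], dtype=float)
    if np.any(conc < 0):
        raise ValueError("standard concentrations must be non-negative")
    if np.ptp(conc) == 0:
        raise ValueError("standard concentrations are all equal; cannot fit a line")
    res = _st.linregress(conc, absb)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return CalibrationCurve(
        standard_name=standard_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        concentration_range=(float(conc.min()), float(conc.max())),
        r_squared=min(r2, 1.0),
    )


def curve_invert(curve: CalibrationCurve, absorbance: float) -> float:
    """Inverse prediction: concentration producing the given response.

    Warns (:class:`ExtrapolationWarning`) when the result falls outside the
    fitted concentration range, including negative concentrations from
    readings below the intercept.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; curve is uninvertible")
    conc = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    if not (min(lo, 0.0) <= conc <= hi):
        warnings.warn(
            f"inverse prediction {conc:.4g} outside calibration range "
            f"[{lo:g}, {hi:g}] for {curve.standard_name}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc


def _per_100g(mass_in_extract_mg: float, ctx: ExtractContext) -> float:
    return mass_in_extract_mg * 100.0 / ctx.sample_mass_g


def quantify_folin_type(
    record: AssayRecord, curve: CalibrationCurve, ctx: ExtractContext
) -> QuantResult:
    """TPC or TFC: equivalents read off a standard curve in ug/mL.

    Chain: measured concentration (ug/mL) x dilution -> extract
    concentration; x extract volume -> ug in extract; rescaled to
    mg / 100 g fresh tissue.
    """
    if record.assay not in (Assay.TPC, Assay.TFC):
        raise ValueError(f"quantify_folin_type cannot handle {record.assay.value}")
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ExtrapolationWarning)
        conc_ug_ml = curve_invert(curve, record.readings["A"])
    if caught:
        flags.append("extrapolated")
    conc_extract = conc_ug_ml * record.dilution_factor
    mass_mg = conc_extract * ctx.extract_volume_ml / 1000.0
    value = _per_100g(mass_mg, ctx)
    if value < 0:
        flags.append("clamped_negative")
        value = 0.0
    return QuantResult(
        record.genotype,
        record.assay,
        record.replicate,
        value,
        FW_UNITS[record.assay],
        "FW",
        tuple(flags),
    )


def quantify_tac(record: AssayRecord, ctx: ExtractContext) -> QuantResult:
    """Monomeric anthocyanins by the pH-differential method.

    A = (A510 - A700) at pH 1.0 minus the same difference at pH 4.5;
    cyanidin-3-glucoside mg/L = A * MW * DF * 1000 / (eps * path).
    Slightly negative A (yellow fruit near the detection limit) clamps
    to zero with a flag rather than erroring.
    """
    if record.assay is not Assay.TAC:
        raise ValueError(f"quantify_tac cannot handle {record.assay.value}")
    r = record.readings
    a = (r["A510_pH1.0"] - r["A700_pH1.0"]) - (r["A510_pH4.5"] - r["A700_pH4.5"])
    flags: list[str] = []
    if -1e-9 < a < 0:  # pure floating-point noise from the double difference
        a = 0.0
    if a < 0:
        warnings.warn(
            f"negative pH-differential absorbance ({a:.4g}) for "
            f"{record.genotype!r}; clamping to 0",
            UserWarning,
            stacklevel=2,
        )
        flags.append("clamped_negative")
        a = 0.0
    mg_per_l = (
        a
        * TAC_MOLAR_MASS
        * record.dilution_factor
        * 1000.0
        / (TAC_EXTINCTION * TAC_PATH_LENGTH)
    )
    mass_mg = mg_per_l * ctx.extract_volume_ml / 1000.0
    value = _per_100g(mass_mg, ctx)
    return QuantResult(
        record.genotype,
        record.assay,
        record.replicate,
        value,
        FW_UNITS[Assay.TAC],
        "FW",
        tuple(flags),
    )


def quantify_abts(
    record: AssayRecord, curve: CalibrationCurve, ctx: ExtractContext
) -> QuantResult:
    """ABTS radical-cation decolorization, reported as Trolox equivalents.

    The curve maps Trolox concentration (mM) to %inhibition of the blank.
    Records outside the 20-80 % inhibition window and blanks away from the
    0.70 +/- 0.02 protocol target are flagged, not rejected.
    """
    if record.assay is not Assay.ABTS:
        raise ValueError(f"quantify_abts cannot handle {record.assay.value}")
    blank = record.readings["A_blank"]
    if blank <= 0:
        raise ValueError("ABTS blank absorbance must be positive")
    flags: list[str] = []
    if abs(blank - ABTS_BLANK_TARGET) > ABTS_BLANK_TOL:
        warnings.warn(
            f"ABTS blank {blank:.3f} outside protocol target "
            f"{ABTS_BLANK_TARGET} +/- {ABTS_BLANK_TOL}",
            UserWarning,
            stacklevel=2,
        )
        flags.append("blank_off_target")
    inhibition = (blank - record.readings["A_sample"]) / blank * 100.0
    lo, hi = ABTS_INHIBITION_WINDOW
    if not lo <= inhibition <= hi:
        flags.append("inhibition_out_of_range")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ExtrapolationWarning)
        conc_mm = curve_invert(curve, inhibition)
    if caught:
        flags.append("extrapolated")
    umol = conc_mm * record.dilution_factor * ctx.extract_volume_ml
    value = umol / ctx.sample_mass_g
    if value < 0:
        flags.append("clamped_negative")
        value = 0.0
    return QuantResult(
        record.genotype,
        record.assay,
        record.replicate,
        value,
        FW_UNITS[Assay.ABTS],
        "FW",
        tuple(flags),
    )


def quantify_frap(
    record: AssayRecord, curve: CalibrationCurve, ctx: ExtractContext
) -> QuantResult:
    """Ferric reducing antioxidant power in umol Trolox equivalents / g FW."""
    if record.assay is not Assay.FRAP:
        raise ValueError(f"quantify_frap cannot handle {record.assay.value}")
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ExtrapolationWarning)
        conc_mm = curve_invert(curve, record.readings["A"])
    if caught:
        flags.append("extrapolated")
    umol = conc_mm * record.dilution_factor * ctx.extract_volume_ml
    value = umol / ctx.sample_mass_g
    if value < 0:
        flags.append("clamped_negative")
        value = 0.0
    return QuantResult(
        record.genotype,
        record.assay,
        record.replicate,
        value,
        FW_UNITS[Assay.FRAP],
        "FW",
        tuple(flags),
    )


def quantify(
    record: AssayRecord,
    ctx: ExtractContext,
    curve: CalibrationCurve | None = None,
) -> QuantResult:
    """Dispatch a record to the quantifier for its assay kind."""
    if record.assay is Assay.TAC:
        return quantify_tac(record, ctx)
    if curve is None:
        raise ValueError(f"{record.assay.value} quantification needs a calibration curve")
    if record.assay in (Assay.TPC, Assay.TFC):
        return quantify_folin_type(record, curve, ctx)
    if record.assay is Assay.FRAP:
        return quantify_frap(record, curve, ctx)
    return quantify_abts(record, curve, ctx)


def fw_to_dw(result: QuantResult, ctx: ExtractContext) -> QuantResult:
    """Rebase a fresh-weight result to per-gram dry weight.

    mg/100 g FW units become mg/g DW (the conventional dry-weight scale);
    umol/g FW becomes umol/g DW.
    """
    if result.basis != "FW":
        raise ValueError("fw_to_dw expects a fresh-weight result")
    dm = ctx.dry_matter_fraction
    if dm is None or not (0.0 < dm < 1.0):
        raise ValueError("dry_matter_fraction must lie strictly in (0, 1)")
    value = result.value
    if "/100 g FW" in result.units:
        value = value / 100.0  # per g FW first
    value = value / dm
    return replace(result, value=value, units=DW_UNITS[result.assay], basis="DW")
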