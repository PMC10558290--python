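"""Domain types, unit conversions, and the packaged ABP reference dataset.

The conversion chain at the center of the census is

    concentration (µM) = abundance (ng ABP / µg total protein) × K / MW (kDa)

where K (µM·kDa per ng/µg) is numerically equal to the cytoplasmic total-
protein mass concentration in g/L.  Two modes are supported:

* *calibrated* (default): K is derived from the actin row of the reference
  table (13.2 µM, 41.8 kDa, 7.99 ng/µg → K ≈ 69.06), which makes the chain
  internally consistent with the published table.
* *first principles*: K is computed from the cell constants (total protein
  mass per cell ÷ cytosolic volume ≈ 148 g/L).  The two disagree by ~2×,
  an ambiguity the published constants do not resolve; see
  :func:`conversion_constant_discrepancy`.

Volumes are carried in fL, concentrations in µM, masses in g throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import IntegrityError, InvalidConstantsError, ValidationError

__all__ = [
    "AVOGADRO",
    "CellConstants",
    "LinearModel",
    "ProteinRecord",
    "abundance_to_concentration",
    "calibrate_conversion_k",
    "concentration_to_molecules",
    "conversion_constant_discrepancy",
    "cytosolic_volume",
    "default_constants",
    "first_principles_k",
    "load_reference_table",
    "molecules_to_concentration",
    "ratio_estimate_abundance",
    "records_to_frame",
    "reference_frame",
    "round_sig",
]

AVOGADRO = 6.02214076e23
#: molecules in 1 µM × 1 fL
_MOLECULES_PER_UM_FL = 1e-21 * AVOGADRO

_REFERENCE_CSV = "abp_reference.csv"
_COMPARISON_CSV = "method_comparison.csv"


@dataclass(frozen=True)
class CellConstants:
    """Physical constants of an average haploid budding-yeast cell.

    Attributes
    ----------
    wet_mass : g, wet weight of one cell.
    density : g/ml.
    cytoplasm_fraction : fraction of cell volume that is cytoplasm
        (the rest is cell wall and organelles).
    protein_mass_per_cell : g of total protein per cell.
    avogadro : mol⁻¹.
    conversion_k : optional calibrated scalar, µM·kDa per (ng/µg).  When
        set it overrides the first-principles value in
        :func:`abundance_to_concentration`.
    """

    wet_mass: float = 6e-11
    density: float = 1.1126
    cytoplasm_fraction: float = 0.5
    protein_mass_per_cell: float = 4e-12
    avogadro: float = AVOGADRO
    conversion_k: float | None = None

    def __post_init__(self) -> None:
        for name in ("wet_mass", "density", "protein_mass_per_cell", "avogadro"):
            if not getattr(self, name) > 0:
                raise InvalidConstantsError(f"{name} must be strictly positive")
        if not 0 < self.cytoplasm_fraction <= 1:
            raise InvalidConstantsError("cytoplasm_fraction must be in (0, 1]")
        if self.conversion_k is not None and not self.conversion_k > 0:
            raise InvalidConstantsError("conversion_k must be strictly positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "CellConstants":
        """Load constants from a YAML or JSON mapping of field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError(f"{path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown constants: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))


@dataclass(frozen=True)
class LinearModel:
    """A fitted line y = slope·x + intercept with its valid x interval."""

    slope: float
    intercept: float
    r_squared: float
    x_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.x_range[0] > self.x_range[1]:
            raise ValidationError("x_range must be ordered")

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def inverse(self, y: float) -> float:
        return (y - self.intercept) / self.slope


@dataclass
class ProteinRecord:
    """Measured and derived quantities for one actin-binding protein.

    ``abundance`` is ng of this protein per µg of total cellular protein;
    ``cytosolic_fraction`` is the portion of the protein's total signal not
    bound to F-actin structures, in [0, 1].  ``oligomer_n`` counts
    polypeptides per functional unit (2 for the capping-protein heterodimer,
    6 for the Srv2 hexamer); concentrations are per polypeptide except for
    capping protein, which is stored as the heterodimer concentration.
    """

    name: str
    common_name: str
    mw: float
    abundance: float
    cellular_conc: float
    molecules_per_cell: float | None = None
    abundance_sd: float | None = None
    cellular_conc_sd: float | None = None
    n_blots: int | None = None
    cytosolic_fraction: float | None = None
    cytosolic_fraction_sd: float | None = None
    cytosolic_conc: float | None = None
    cytosolic_conc_sd: float | None = None
    binds_f_actin: bool = False
    binds_g_actin: bool = False
    oligomer_n: int = 1
    method: str = "western"

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValidationError(f"{self.name}: mw must be > 0")
        if self.abundance < 0:
            raise ValidationError(f"{self.name}: abundance must be >= 0")
        if self.cytosolic_fraction is not None and not 0 <= self.cytosolic_fraction <= 1:
            raise ValidationError(f"{self.name}: cytosolic_fraction outside [0, 1]")
        if (
            self.cytosolic_conc is not None
            and self.cellular_conc is not None
            and self.cytosolic_conc > self.cellular_conc + 1e-9
        ):
            raise ValidationError(f"{self.name}: cytosolic_conc exceeds cellular_conc")
        if self.oligomer_n < 1:
            raise ValidationError(f"{self.name}: oligomer_n must be >= 1")


def cytosolic_volume(constants: CellConstants | None = None) -> float:
    """Cytosolic volume of one cell in fL.

    wet mass / density gives the whole-cell volume; the cytoplasm fraction
    removes the cell wall and organelles.  Defaults give ≈27.0 fL.
    """
    c = constants or CellConstants()
    return c.wet_mass / c.density * 1e12 * c.cytoplasm_fraction


def first_principles_k(constants: CellConstants | None = None) -> float:
    """Conversion constant from the stated cell constants.

    Equals the cytoplasmic total-protein mass concentration in g/L
    (≈148 g/L for the defaults).
    """
    c = constants or CellConstants()
    return c.protein_mass_per_cell / (cytosolic_volume(c) * 1e-15)


def calibrate_conversion_k(conc: float, mw: float, abundance: float) -> float:
    """Derive K (µM·kDa per ng/µg) from one protein with all three known."""
    if abundance <= 0 or mw <= 0 or conc <= 0:
        raise ValidationError("calibration requires strictly positive inputs")
    return conc * mw / abundance


def default_constants(calibrated: bool = True) -> CellConstants:
    """Default cell constants; with ``calibrated`` the conversion constant
    is derived from the actin row of the packaged reference table."""
    if not calibrated:
        return CellConstants()
    act1 = next(r for r in load_reference_table() if r.name == "Act1")
    k = calibrate_conversion_k(act1.cellular_conc, act1.mw, act1.abundance)
    return CellConstants(conversion_k=k)


def conversion_constant_discrepancy(constants: CellConstants | None = None) -> dict:
    """Report the mismatch between the calibrated and first-principles K."""
    c = constants or default_constants()
    k_cal = c.conversion_k
    k_fp = first_principles_k(c)
    return {
        "calibrated_k": k_cal,
        "first_principles_k": k_fp,
        "ratio": None if k_cal is None else k_fp / k_cal,
        "note": "K equals cytoplasmic protein concentration in g/L; the "
        "published table is internally consistent with ~69 g/L, while the "
        "stated per-cell protein mass and volume imply ~148 g/L.",
    }


def abundance_to_concentration(
    abundance: float, mw: float, constants: CellConstants | None = None
) -> float:
    """Convert blot abundance (ng/µg) to cellular concentration (µM).

    Linear in abundance, inverse in molecular weight.  Uses
    ``constants.conversion_k`` when set, else the first-principles K.
    """
    if mw <= 0:
        raise ValidationError("mw must be > 0")
    if abundance < 0:
        raise ValidationError("abundance must be >= 0")
    c = constants or default_constants()
    k = c.conversion_k if c.conversion_k is not None else first_principles_k(c)
    return abundance * k / mw


def concentration_to_molecules(
    conc: float, volume: float, avogadro: float = AVOGADRO
) -> float:
    """Molecules per cell from concentration (µM) and volume (fL)."""
    if conc < 0:
        raise ValidationError("concentration must be >= 0")
    if volume <= 0:
        raise ValidationError("volume must be > 0")
    return conc * volume * avogadro * 1e-21


def molecules_to_concentration(
    count: float, volume: float, avogadro: float = AVOGADRO
) -> float:
    """Inverse of :func:`concentration_to_molecules` (µM)."""
    if count < 0:
        raise ValidationError("count must be >= 0")
    if volume <= 0:
        raise ValidationError("volume must be > 0")
    return count / (volume * avogadro * 1e-21)


def ratio_estimate_abundance(
    ref_abundance: float,
    divisor: float,
    mw: float,
    constants: CellConstants | None = None,
) -> tuple[float, float]:
    """Estimate a protein's abundance and concentration from a molar-ratio
    reference (e.g. Tpm2 at one-sixth of Tpm1's abundance).

    Returns ``(abundance ng/µg, concentration µM)`` where the concentration
    uses the *target* protein's molecular weight.
    """
    if divisor <= 0:
        raise ValidationError("divisor must be > 0")
    abundance = ref_abundance / divisor
    return abundance, abundance_to_concentration(abundance, mw, constants)


# ---------------------------------------------------------------------------
# packaged reference data

_BOOL_MAP = {"True": True, "False": False, True: True, False: False}


def _data_path(name: str):
    return resources.files("abpcensus.data").joinpath(name)


def reference_frame() -> pd.DataFrame:
    """The packaged reference table as a DataFrame (printed values verbatim)."""
    with resources.as_file(_data_path(_REFERENCE_CSV)) as p:
        return pd.read_csv(p)


def method_comparison_frame() -> pd.DataFrame:
    """Packaged per-protein concentrations by quantification method
    (Western blot, GFP fluorescence, mass-spectrometry meta-analysis);
    missing entries mean the method was not applied to that protein."""
    with resources.as_file(_data_path(_COMPARISON_CSV)) as p:
        return pd.read_csv(p)


def _opt(value, cast=float):
    return None if pd.isna(value) else cast(value)


def load_reference_table() -> list[ProteinRecord]:
    """Load the packaged reference dataset (actin + 14 ABPs).

    Raises :class:`IntegrityError` if the packaged file is malformed.
    """
    df = reference_frame()
    expected = {
        "name", "common_name", "mw_kda", "abundance_ng_per_ug", "abundance_sd",
        "n_blots", "cellular_conc_um", "cellular_conc_sd", "molecules_per_cell",
        "pct_free_cytosol", "pct_free_cytosol_sd", "cytosolic_conc_um",
        "cytosolic_conc_sd", "binds_f_actin", "binds_g_actin", "oligomer_n",
        "method",
    }
    if set(df.columns) != expected:
        raise IntegrityError("reference table columns do not match the schema")
    records = []
    try:
        for row in df.itertuples(index=False):
            frac = _opt(row.pct_free_cytosol)
            frac_sd = _opt(row.pct_free_cytosol_sd)
            records.append(
                ProteinRecord(
                    name=row.name,
                    common_name=row.common_name,
                    mw=float(row.mw_kda),
                    abundance=float(row.abundance_ng_per_ug),
                    abundance_sd=_opt(row.abundance_sd),
                    n_blots=_opt(row.n_blots, int),
                    cellular_conc=float(row.cellular_conc_um),
                    cellular_conc_sd=_opt(row.cellular_conc_sd),
                    molecules_per_cell=_opt(row.molecules_per_cell),
                    cytosolic_fraction=None if frac is None else frac / 100.0,
                    cytosolic_fraction_sd=None if frac_sd is None else frac_sd / 100.0,
                    cytosolic_conc=_opt(row.cytosolic_conc_um),
                    cytosolic_conc_sd=_opt(row.cytosolic_conc_sd),
                    binds_f_actin=_BOOL_MAP[row.binds_f_actin],
                    binds_g_actin=_BOOL_MAP[row.binds_g_actin],
                    oligomer_n=int(row.oligomer_n),
                    method=row.method,
                )
            )
    except (ValidationError, KeyError, TypeError) as exc:
        raise IntegrityError(f"packaged reference data corrupt: {exc}") from exc
    if len(records) != 15:
        raise IntegrityError(f"expected 15 reference records, found {len(records)}")
    return records


def records_to_frame(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Serialize records back to the reference CSV schema (round-trips with
    :func:`load_reference_table`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "common_name": r.common_name,
                "mw_kda": r.mw,
                "abundance_ng_per_ug": r.abundance,
                "abundance_sd": r.abundance_sd,
                "n_blots": r.n_blots,
                "cellular_conc_um": r.cellular_conc,
                "cellular_conc_sd": r.cellular_conc_sd,
                "molecules_per_cell": r.molecules_per_cell,
                "pct_free_cytosol": None
                if r.cytosolic_fraction is None
                else r.cytosolic_fraction * 100.0,
                "pct_free_cytosol_sd": None
                if r.cytosolic_fraction_sd is None
                else r.cytosolic_fraction_sd * 100.0,
                "cytosolic_conc_um": r.cytosolic_conc,
                "cytosolic_conc_sd": r.cytosolic_conc_sd,
                "binds_f_actin": r.binds_f_actin,
                "binds_g_actin": r.binds_g_actin,
                "oligomer_n": r.oligomer_n,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report output convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)
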