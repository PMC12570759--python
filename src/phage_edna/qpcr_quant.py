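"""Absolute quantification of environmental DNA (eDNA) from qPCR data.

Free, unencapsidated DNA in a phage lysate is quantified by qPCR against a
log-linear standard curve.  Because the high temperature of the PCR itself
releases packaged phage DNA, the phage eDNA present *before* the reaction
is estimated by subtraction: the concentration measured in a DNase-treated
aliquot (which retains only the PCR-released background) is subtracted
from the concentration measured in a buffer-only aliquot (original eDNA
plus the same background).  Mass concentrations are converted to genome
copies per millilitre for comparison with particle titers.

All derived quantities carry first-order standard uncertainties
(:class:`~phage_edna.uncertainty.UValue`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .uncertainty import UValue

__all__ = [
    "AVOGADRO",
    "BP_MOLAR_MASS",
    "DEFAULT_GENOMES",
    "GenomeSpec",
    "StandardCurve",
    "InsufficientDataError",
    "fit_standard_curve",
    "ct_to_concentration",
    "subtract_dnase_background",
    "mass_conc_to_copies",
    "copies_per_particle",
    "pool_estimates",
    "PooledEstimate",
    "read_ct_table",
    "read_curve_points",
    "quantify_lysates",
]

AVOGADRO = 6.02214076e23
#: Mean molar mass of a double-stranded DNA base pair, g/mol. The standard
#: convention for copy-number calculations; overridable per call.
BP_MOLAR_MASS = 650.0

TREATMENTS = ("untreated", "buffer_only", "dnase")


class InsufficientDataError(ValueError):
    """Raised when a fit or pooled estimate has too few data points."""


@dataclass(frozen=True)
class GenomeSpec:
    """A genome used to convert DNA mass into copy numbers."""

    name: str
    length_bp: int
    role: str = "phage"  # "phage" or "bacterial"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be > 0, got {self.length_bp}")


#: Default genome lengths (bp). These are literature values for the model
#: system — neither phage genome length is part of the measured data — and
#: every conversion accepts an explicit :class:`GenomeSpec` instead.
DEFAULT_GENOMES = {
    "phage_2972": GenomeSpec("phage_2972", 34_704, "phage"),
    "phage_858": GenomeSpec("phage_858", 35_543, "phage"),
    "s_thermophilus_dgcc7710": GenomeSpec(
        "s_thermophilus_dgcc7710", 1_850_000, "bacterial"
    ),
}


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR calibration: Ct = slope * log10(conc) + intercept.

    ``slope`` is expected negative (more template -> earlier threshold);
    a slope of -1/log10(2) = -3.3219 corresponds to perfect doubling each
    cycle, i.e. an amplification efficiency of 100%.
    """

    slope: float
    intercept: float
    residual_sd: float
    n_points: int
    slope_se: float = float("nan")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency derived from the slope (1.0 = 100%)."""
        if self.slope >= 0:
            raise ValueError("efficiency is defined only for negative slopes")
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, conc: float) -> float:
        """Forward map: expected Ct at a given concentration."""
        if conc <= 0:
            raise ValueError("concentration must be positive")
        return self.slope * math.log10(conc) + self.intercept


def fit_standard_curve(
    known_concs: Sequence[float], cts: Sequence[float]
) -> StandardCurve:
    """Fit a standard curve by OLS of Ct on log10(concentration).

    Requires at least three distinct positive concentrations.  The
    residual standard deviation comes from the residual mean square with
    n - 2 degrees of freedom.
    """
    concs = np.asarray(known_concs, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if concs.shape != ct.shape:
        raise ValueError("known_concs and cts must have the same length")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive for log10 transform")
    if len(np.unique(concs)) < 3:
        raise InsufficientDataError(
            "standard curve needs >= 3 distinct concentrations, got "
            f"{len(np.unique(concs))}"
        )
    x = np.log10(concs)
    res = stats.linregress(x, ct)
    fitted = res.intercept + res.slope * x
    dof = len(ct) - 2
    residual_sd = float(np.sqrt(np.sum((ct - fitted) ** 2) / dof)) if dof else 0.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        n_points=len(ct),
        slope_se=float(res.stderr),
    )


def ct_to_concentration(curve: StandardCurve, cts: Sequence[float]) -> UValue:
    """Invert replicate Ct values through a standard curve.

    The mean Ct is mapped to ``10**((mean_ct - intercept) / slope)``.  On
    the log10 scale the uncertainty combines the replicate standard error
    of the mean and the curve's residual scatter, each divided by |slope|,
    in quadrature; the result is converted to a concentration sd
    multiplicatively (first order: sd = conc * ln10 * sd_log10).
    """
    if curve.slope >= 0:
        raise ValueError(f"curve slope must be negative, got {curve.slope}")
    ct = np.asarray(cts, dtype=float)
    if ct.size == 0:
        raise InsufficientDataError("need at least one Ct replicate")
    mean_ct = float(ct.mean())
    sem = float(ct.std(ddof=1) / math.sqrt(ct.size)) if ct.size > 1 else 0.0
    log10_conc = (mean_ct - curve.intercept) / curve.slope
    sd_log10 = math.hypot(sem / abs(curve.slope), curve.residual_sd / abs(curve.slope))
    conc = 10.0**log10_conc
    return UValue(conc, conc * math.log(10.0) * sd_log10)


def subtract_dnase_background(buffer_only: UValue, dnase_treated: UValue) -> UValue:
    """DNase-subtraction estimator of pre-existing eDNA.

    Both inputs must be in the same units.  Uncertainties combine in
    quadrature.  Negative results are returned as-is — clamping at zero
    would bias pooled means — and callers should flag them.
    """
    return buffer_only - dnase_treated


def mass_conc_to_copies(
    conc: UValue,
    genome: GenomeSpec,
    bp_molar_mass: float = BP_MOLAR_MASS,
) -> UValue:
    """Convert a mass concentration (ng/uL) into genome copies per mL.

    copies/mL = conc[ng/uL] * 1000[uL/mL] * 1e-9[g/ng] * N_A
                / (length_bp * m_bp)

    with ``m_bp`` the mean dsDNA base-pair molar mass in g/mol.  The
    relative uncertainty of the input is preserved exactly.
    """
    if genome.length_bp <= 0:
        raise ValueError("genome length must be positive")
    if bp_molar_mass <= 0:
        raise ValueError("bp molar mass must be positive")
    factor = 1000.0 * 1e-9 * AVOGADRO / (genome.length_bp * bp_molar_mass)
    return conc.scale(factor)


def copies_per_particle(copies_per_ml: UValue, particles_per_ml: float) -> UValue:
    """Genome copies per infective (pfu) or colony-forming (cfu) particle."""
    if particles_per_ml <= 0:
        raise ValueError(
            f"particles_per_mL must be positive, got {particles_per_ml}"
        )
    return copies_per_ml.scale(1.0 / particles_per_ml)


@dataclass(frozen=True)
class PooledEstimate:
    """Unweighted pool of per-lysate estimates.

    ``sd_spread`` is the standard error of the mean computed from the
    scatter of the point estimates; ``sd_propagated`` combines the input
    standard uncertainties in quadrature (sqrt(sum sd_i^2)/n).  Which is
    appropriate depends on whether between-lysate variation or
    measurement error dominates, so both are reported.
    """

    mean: float
    sd_spread: float
    sd_propagated: float
    n: int

    def as_uvalue(self, which: str = "spread") -> UValue:
        sd = self.sd_spread if which == "spread" else self.sd_propagated
        return UValue(self.mean, sd)


def pool_estimates(estimates: Sequence[UValue]) -> PooledEstimate:
    """Pool independent estimates into an unweighted mean with both a
    spread-based and a propagation-based standard error."""
    if len(estimates) == 0:
        raise InsufficientDataError("cannot pool an empty list of estimates")
    values = np.array([e.value for e in estimates], dtype=float)
    sds = np.array([e.sd for e in estimates], dtype=float)
    n = len(values)
    mean = float(values.mean())
    sd_spread = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    sd_propagated = float(np.sqrt(np.sum(sds**2)) / n)
    return PooledEstimate(mean, sd_spread, sd_propagated, n)


# ---------------------------------------------------------------------------
# Tabular I/O and the per-lysate pipeline
# ---------------------------------------------------------------------------

CT_TABLE_COLUMNS = ["sample_id", "primer_set", "treatment", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct table CSV (`sample_id,primer_set,treatment,replicate,ct`)
    and validate it."""
    df = pd.read_csv(path)
    missing = [c for c in CT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    if not np.all(np.isfinite(df["ct"].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite")
    bad = set(df["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(
            f"unknown treatments {sorted(bad)}; expected one of {TREATMENTS}"
        )
    dup = df.duplicated(subset=["sample_id", "primer_set", "treatment", "replicate"])
    if dup.any():
        raise ValueError(
            "duplicate replicate ids within (sample, primer_set, treatment): "
            f"{df.loc[dup, ['sample_id', 'primer_set', 'treatment', 'replicate']].to_dict('records')}"
        )
    return df


def read_curve_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Read standard-curve points CSV (`conc_ng_per_ul,ct`)."""
    df = pd.read_csv(path)
    for col in ("conc_ng_per_ul", "ct"):
        if col not in df.columns:
            raise ValueError(f"curve CSV is missing column {col!r}")
    return df["conc_ng_per_ul"].to_numpy(dtype=float), df["ct"].to_numpy(dtype=float)


def quantify_lysates(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    genome: GenomeSpec | None = None,
) -> pd.DataFrame:
    """Per-lysate eDNA quantification: invert Ct replicates per treatment,
    apply the DNase subtraction, and (optionally) convert to copies/mL.

    Returns one row per (sample_id, primer_set) with raw concentrations,
    the DNase-subtracted eDNA estimate, a flag for negative subtraction
    results, and parentheses-formatted strings.
    """
    validate_ct_table(ct_table)
    rows = []
    for (sample, primer), grp in ct_table.groupby(["sample_id", "primer_set"]):
        concs: dict[str, UValue] = {}
        for treatment, sub in grp.groupby("treatment"):
            concs[treatment] = ct_to_concentration(curve, sub["ct"].to_numpy())
        row: dict[str, object] = {"sample_id": sample, "primer_set": primer}
        for treatment in TREATMENTS:
            uv = concs.get(treatment)
            row[f"conc_{treatment}_ng_per_ul"] = uv.value if uv else np.nan
            row[f"conc_{treatment}_sd"] = uv.sd if uv else np.nan
        if "buffer_only" in concs and "dnase" in concs:
            edna = subtract_dnase_background(concs["buffer_only"], concs["dnase"])
            row["edna_ng_per_ul"] = edna.value
            row["edna_sd"] = edna.sd
            row["edna_formatted"] = str(edna)
            row["negative_flag"] = edna.value < 0
            if genome is not None:
                copies = mass_conc_to_copies(edna, genome)
                row["copies_per_ml"] = copies.value
                row["copies_per_ml_sd"] = copies.sd
                row["copies_formatted"] = str(copies)
        rows.append(row)
    return pd.DataFrame(rows)
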