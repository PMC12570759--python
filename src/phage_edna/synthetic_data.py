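"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without wet-lab data or
downloads: a pair of ~35 kb phage genomes about 90% identical with their
differences clustered in one variable region; qPCR Ct tables generated
from a log-linear standard curve with Gaussian cycle noise; Poisson plate
counts whose mean is modulated by condition multipliers and a unimodal
MOI response; and multinomial spacer acquisition over protospacers with
a 90/10 CR1/CR3 array split and an optional bias toward a target set
(the "eDNA donates sequence" world).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .protospacer_scan import Protospacer, Region
from .qpcr_quant import StandardCurve

__all__ = [
    "ScenarioConfig",
    "gen_phage_pair",
    "sim_qpcr",
    "moi_response",
    "sim_bim_assay",
    "sim_spacer_acquisition",
    "sim_spacer_acquisition_counts",
    "spacer_target_hit_probability",
    "pairwise_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Ct assigned to reactions whose true concentration is zero (censored
#: "no amplification" flag value).
CENSORED_CT = 40.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a full simulated experiment.

    Defaults emulate the model system: a ~34.7 kb phage genome whose
    differences from its relative cluster in a variable region (chosen so
    the pair's overall identity is ~90%), lysate titers of ~2e8 pfu/mL,
    ~0.5 ng/uL phage eDNA over ~0.14 ng/uL bacterial eDNA, a spacer
    acquisition rate of ~1e-6 per cell, 90% of acquisitions in the CR1
    array, BIM generation peaking at an MOI of 0.35, and a 40% BIM
    reduction when eDNA is digested (DNase condition multiplier 0.6).
    """

    seed: int = 0
    genome_len: int = 34_704
    variable_region: Region = field(
        default_factory=lambda: Region("phage_a", 28_505, 32_484)
    )
    divergence_in: float = 0.65
    divergence_out: float = 0.0265
    titer_pfu_per_ml: float = 2e8
    edna_ng_per_ul: float = 0.5
    bacterial_edna_ng_per_ul: float = 0.14
    acquisition_rate: float = 1e-6
    cr1_fraction: float = 0.9
    condition_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "untreated": 1.0,
            "buffer_only": 1.0,
            "dnase": 0.6,
            "supplemented:fragment_a": 1.7,
        }
    )
    moi_peak: float = 0.35
    moi_width: float = 1.0
    cells_per_plate: float = 3e7
    day_effect_sd: float = 0.2
    #: Extra-Poisson noise: counts drawn as Gamma-Poisson with variance
    #: mean + overdispersion * mean^2. 0 recovers pure Poisson.
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("divergence_in", "divergence_out", "cr1_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (
            0 <= self.variable_region.start
            and self.variable_region.end <= self.genome_len
        ):
            raise ValueError(
                f"variable region {self.variable_region} outside genome of "
                f"length {self.genome_len}"
            )

    @classmethod
    def from_json(cls, source) -> "ScenarioConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if "variable_region" in payload:
            payload["variable_region"] = Region(**payload["variable_region"])
        return cls(**payload)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["condition_multipliers"] = dict(self.condition_multipliers)
        return json.dumps(payload, indent=2)


def _rng(config_seed: int, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config_seed if seed is None else seed)


def gen_phage_pair(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[SeqRecord, SeqRecord]:
    """Generate two related phage genomes with clustered divergence.

    Genome A is uniform random; genome B substitutes each base with
    probability ``divergence_in`` inside the variable region and
    ``divergence_out`` elsewhere (substitutions always change the base,
    so the divergence rate is the expected mismatch rate).  No indels:
    coordinates stay comparable between the pair.
    """
    rng = _rng(config.seed, seed)
    n = config.genome_len
    a = rng.integers(0, 4, size=n)
    region = config.variable_region
    rate = np.full(n, config.divergence_out)
    rate[region.start : region.end] = config.divergence_in
    substitute = rng.random(n) < rate
    # A substituted base moves to one of the three other bases.
    shift = rng.integers(1, 4, size=n)
    b = np.where(substitute, (a + shift) % 4, a)
    seq_a = _BASES[a].tobytes().decode()
    seq_b = _BASES[b].tobytes().decode()
    return (
        SeqRecord(Seq(seq_a), id="phage_a", description="synthetic phage genome"),
        SeqRecord(
            Seq(seq_b),
            id="phage_b",
            description="synthetic related phage genome",
        ),
    )


def pairwise_identity(rec_a, rec_b) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    a = str(rec_a.seq if hasattr(rec_a, "seq") else rec_a)
    b = str(rec_b.seq if hasattr(rec_b, "seq") else rec_b)
    if len(a) != len(b):
        raise ValueError("sequences must be equal length (no-indel model)")
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    return float(np.mean(arr_a == arr_b))


def sim_qpcr(
    true_concs: Mapping[tuple[str, str, str], float],
    curve: StandardCurve,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table from true concentrations.

    ``true_concs`` maps (sample_id, primer_set, treatment) to the true
    concentration in the reaction; each replicate's Ct is the curve's
    forward map plus Gaussian cycle noise.  Zero concentrations yield the
    censored Ct value (no amplification) and are flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (sample, primer, treatment), conc in true_concs.items():
        for rep in range(1, replicates + 1):
            if conc > 0:
                ct = (
                    curve.slope * math.log10(conc)
                    + curve.intercept
                    + rng.normal(0.0, noise_sd)
                )
                censored = False
            else:
                ct = CENSORED_CT
                censored = True
            rows.append(
                {
                    "sample_id": sample,
                    "primer_set": primer,
                    "treatment": treatment,
                    "replicate": rep,
                    "ct": ct,
                    "censored": censored,
                }
            )
    return pd.DataFrame(rows)


def moi_response(
    moi: float | np.ndarray, peak_moi: float = 0.35, width: float = 1.0
) -> float | np.ndarray:
    """Relative BIM-generation rate as a function of MOI.

    A unimodal log-normal-shaped curve on log MOI: maximum 1 at
    ``peak_moi``, falling to 0 as MOI goes to 0 or infinity.  ``width``
    is the sd of the bell in log-MOI units.
    """
    moi = np.asarray(moi, dtype=float)
    if np.any(moi < 0):
        raise ValueError("MOI must be >= 0")
    if peak_moi <= 0 or width <= 0:
        raise ValueError("peak_moi and width must be positive")
    with np.errstate(divide="ignore"):
        z = np.where(moi > 0, np.log(moi / peak_moi), -np.inf)
    resp = np.exp(-(z**2) / (2.0 * width**2))
    resp = np.where(moi > 0, resp, 0.0)
    return float(resp) if resp.ndim == 0 else resp


def sim_bim_assay(
    config: ScenarioConfig,
    conditions: Sequence[str] | None = None,
    mois: Sequence[float] = (0.35,),
    n_days: int = 6,
    plates_per_condition: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate BIM plate counts.

    Colonies are rare independent events, so each plate's CFU is Poisson
    with mean ``cells x acquisition_rate x multiplier(condition) x
    moi_response(moi)``; a shared log-normal day multiplier models the
    day-to-day culture variability the baseline normalisation removes.
    """
    rng = _rng(config.seed, seed)
    if conditions is None:
        conditions = list(config.condition_multipliers)
    multipliers = dict(config.condition_multipliers)
    missing = [c for c in conditions if c not in multipliers]
    if missing:
        raise ValueError(f"no condition multiplier configured for {missing}")
    if any(multipliers[c] <= 0 for c in conditions):
        raise ValueError("condition multipliers must be positive")
    rows = []
    for day in range(1, n_days + 1):
        day_mult = rng.lognormal(0.0, config.day_effect_sd)
        for moi in mois:
            base_mean = (
                config.cells_per_plate
                * config.acquisition_rate
                * day_mult
                * moi_response(moi, config.moi_peak, config.moi_width)
            )
            for condition in conditions:
                mean = base_mean * multipliers[condition]
                if config.overdispersion > 0 and mean > 0:
                    lam = rng.gamma(
                        1.0 / config.overdispersion,
                        config.overdispersion * mean,
                        size=plates_per_condition,
                    )
                    cfu = rng.poisson(lam)
                else:
                    cfu = rng.poisson(mean, size=plates_per_condition)
                for plate, count in enumerate(cfu, start=1):
                    rows.append(
                        {
                            "day_id": f"day{day}",
                            "lysate_id": f"lysate{day}",
                            "condition": condition,
                            "moi": float(moi),
                            "cfu": int(count),
                            "plate": plate,
                        }
                    )
    return pd.DataFrame(rows)


def sim_spacer_acquisition(
    n_bims: int,
    protospacers: Sequence[Protospacer],
    target_set: Sequence[Protospacer],
    bias_fraction: float = 0.0,
    cr1_fraction: float = 0.9,
    seed: int = 0,
) -> list[SeqRecord]:
    """Simulate which spacer each BIM acquires.

    Each BIM first draws its array: CR1 with probability ``cr1_fraction``
    (only CR1 acquisitions can hit the CR1 target set; CR3 acquisitions
    are recorded but never count as target hits).  A CR1 spacer comes
    from ``target_set`` with probability ``bias_fraction`` (the world
    where eDNA donates sequence) and uniformly from all ``protospacers``
    otherwise.  Records carry ``array``, ``source`` and ``is_target``
    annotations.
    """
    if not (0.0 <= bias_fraction <= 1.0):
        raise ValueError("bias_fraction must lie in [0, 1]")
    if not (0.0 <= cr1_fraction <= 1.0):
        raise ValueError("cr1_fraction must lie in [0, 1]")
    if len(protospacers) == 0:
        raise ValueError("protospacer list must be non-empty")
    if bias_fraction > 0 and len(target_set) == 0:
        raise ValueError("target_set must be non-empty when bias_fraction > 0")
    target_keys = {(p.start, p.end, p.strand) for p in target_set}
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_bims):
        array = "CR1" if rng.random() < cr1_fraction else "CR3"
        if array == "CR1" and bias_fraction > 0 and rng.random() < bias_fraction:
            proto = target_set[rng.integers(len(target_set))]
            source = "target"
        else:
            proto = protospacers[rng.integers(len(protospacers))]
            source = "genome"
        is_target = (
            array == "CR1" and (proto.start, proto.end, proto.strand) in target_keys
        )
        rec = SeqRecord(
            Seq(proto.seq),
            id=f"bim{i}_{array.lower()}",
            description=f"array={array} source={source} is_target={is_target}",
        )
        rec.annotations.update(
            array=array, source=source, is_target=bool(is_target)
        )
        records.append(rec)
    return records


def spacer_target_hit_probability(
    n_protospacers: int,
    n_targets: int,
    bias_fraction: float = 0.0,
    cr1_fraction: float = 0.9,
) -> float:
    """Per-BIM probability of a target hit under the acquisition model.

    A hit requires a CR1 acquisition whose spacer lies in the target set:
    ``cr1 * (bias + (1 - bias) * n_targets / n_protospacers)``.  This is
    the analytic counterpart of :func:`sim_spacer_acquisition` (and its
    batch form), against which the zero-detection probability
    ``(1 - p)^n`` can be calibrated by Monte Carlo.
    """
    if n_protospacers <= 0:
        raise ValueError("n_protospacers must be positive")
    frac = n_targets / n_protospacers
    return cr1_fraction * (bias_fraction + (1.0 - bias_fraction) * frac)


def sim_spacer_acquisition_counts(
    n_replicates: int,
    n_bims: int,
    n_protospacers: int,
    n_targets: int,
    bias_fraction: float = 0.0,
    cr1_fraction: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Batch form of :func:`sim_spacer_acquisition`: target-hit counts.

    Runs ``n_replicates`` independent acquisition experiments of
    ``n_bims`` BIMs each and returns the number of target hits per
    replicate.  The generative chain is identical to the per-record
    simulator — array choice, bias coin, uniform protospacer draw — but
    carried as arrays so calibration runs of 1e5 replicates stay cheap.
    The target set is taken to be the first ``n_targets`` protospacers.
    """
    if n_protospacers <= 0:
        raise ValueError("n_protospacers must be positive")
    if not (0 <= n_targets <= n_protospacers):
        raise ValueError("n_targets must lie in [0, n_protospacers]")
    rng = np.random.default_rng(seed)
    shape = (n_replicates, n_bims)
    is_cr1 = rng.random(shape) < cr1_fraction
    biased = rng.random(shape) < bias_fraction
    uniform_draw = rng.integers(0, n_protospacers, size=shape)
    uniform_hit = uniform_draw < n_targets
    hits = is_cr1 & (biased | (~biased & uniform_hit))
    return hits.sum(axis=1)
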