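"""Synthetic qPCR melt and amplification generator.

Real melt curves come from a saturating intercalating dye reporting the
fraction of DNA still double-stranded as temperature ramps 60->90 degC.  This
module stands in for the instrument: each amplicon is decomposed into a few
contiguous melting domains, each domain gets a GC/length-derived melting
temperature (classical salt-adjusted rule), and overall helicity is a
weight-averaged two-state logistic in temperature.  Fluorescence interpolates
between sloped double-stranded and single-stranded baselines, with per-run
amplitude jitter, a small per-run Tm offset, and additive noise — enough
intraspecific variation to make classification non-trivial while keeping
species signatures sequence-determined.

The model is deliberately a controllable phenomenological stand-in, not
nearest-neighbor thermodynamics: the requirement is sequence-sensitive,
reproducible signatures, not thermodynamic accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .amplicon import IUPAC_EXPANSION, AmpliconRecord, read_fasta

__all__ = [
    "MeltModelParams",
    "AmplificationParams",
    "TemperatureGrid",
    "MeltRun",
    "domain_decompose",
    "predict_domain_tm",
    "simulate_melt",
    "simulate_amplification",
    "make_labeled_dataset",
    "write_runs_csv",
    "read_runs_csv",
]


@dataclasses.dataclass(frozen=True)
class TemperatureGrid:
    """Uniform melt-stage temperature grid (default 60-90 degC at 0.1 degC)."""

    start: float = 60.0
    stop: float = 90.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.stop > self.start and self.step > 0):
            raise ValueError("grid must be strictly increasing with positive step")

    @property
    def temperatures(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


@dataclasses.dataclass(frozen=True)
class MeltModelParams:
    """Parameters of the multi-domain two-state melt model.

    Tm of a domain follows the salt-adjusted GC rule
    ``81.5 + 16.6 log10([Na+]) + 0.41 (%GC) - 675/length``.
    ``transition_width`` is the logistic scale (degC) of each domain's
    helix-to-coil transition.  Baselines are (intercept RFU at 60 degC,
    slope RFU/degC): the double-stranded baseline must sit above the
    single-stranded one, since the dye only fluoresces on duplex DNA.
    """

    n_domains: int = 3
    tm_base: float = 81.5
    tm_gc_coeff: float = 0.41     # degC per %GC
    tm_length_coeff: float = 675.0  # degC * bp
    sodium_molar: float = 0.05
    transition_width: float = 0.9   # degC
    ds_baseline: tuple[float, float] = (2600.0, -9.0)
    ss_baseline: tuple[float, float] = (350.0, -1.5)
    noise_sd: float = 6.0           # RFU
    amplitude_jitter_sd: float = 0.05  # fractional
    tm_jitter_sd: float = 0.15      # degC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ds_baseline[0] <= self.ss_baseline[0]:
            raise ValueError("double-stranded baseline must exceed single-stranded at 60 degC")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


@dataclasses.dataclass(frozen=True)
class AmplificationParams:
    """Logistic-plateau amplification model on a 40-cycle protocol."""

    initial_copies: float = 1e4
    efficiency: float = 0.95
    cycles: int = 40
    plateau_cap: float = 1e12
    baseline_rfu: float = 100.0
    plateau_nfu: float = 15.0   # target plateau-minus-baseline signal
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")
        if self.cycles < 1:
            raise ValueError("cycles must be positive")
        if self.plateau_cap <= self.initial_copies:
            raise ValueError("plateau_cap must exceed initial_copies")
        if self.initial_copies < 0:
            raise ValueError("initial_copies must be non-negative")


@dataclasses.dataclass
class MeltRun:
    """One reaction's fluorescence series on a uniform x grid.

    ``x`` is temperature (degC) for melt-stage runs and cycle index for
    amplification-stage runs.
    """

    run_id: str
    stage: str  # "melt" | "amplification"
    x: np.ndarray
    fluorescence: np.ndarray
    species_label: str = ""
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.stage not in ("melt", "amplification"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.x.shape != self.fluorescence.shape or self.x.size < 8:
            raise ValueError("x and fluorescence must share a length >= 8")
        steps = np.diff(self.x)
        if np.any(steps <= 0):
            raise ValueError("x must be strictly increasing")
        if self.stage == "melt":
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
                raise ValueError("melt-stage grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.x[1] - self.x[0])


def _fractional_gc(ch: str) -> float:
    exp = IUPAC_EXPANSION[ch]
    return len(exp & {"G", "C"}) / len(exp)


def domain_decompose(amplicon: AmpliconRecord,
                     n_domains: int) -> list[tuple[str, float, float]]:
    """Split an amplicon into contiguous near-equal melting domains.

    Returns ``(subsequence, gc_fraction, weight)`` per domain; the length
    remainder is distributed left-to-right and weight is the length share.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    length = len(amplicon)
    if n_domains > length:
        raise ValueError(f"n_domains={n_domains} exceeds amplicon length {length}")
    base, rem = divmod(length, n_domains)
    out = []
    pos = 0
    for d in range(n_domains):
        seg_len = base + (1 if d < rem else 0)
        seg = amplicon.sequence[pos:pos + seg_len]
        pos += seg_len
        gc = sum(_fractional_gc(c) for c in seg) / seg_len
        out.append((seg, gc, seg_len / length))
    return out


def predict_domain_tm(gc_fraction: float, length: float,
                      params: MeltModelParams) -> float:
    """Salt-adjusted GC-rule melting temperature for one domain (degC)."""
    if not (math.isfinite(gc_fraction) and math.isfinite(length)):
        raise ValueError("inputs must be finite")
    if not (0.0 <= gc_fraction <= 1.0) or length <= 0:
        raise ValueError("gc_fraction in [0,1] and length > 0 required")
    return (params.tm_base
            + 16.6 * math.log10(params.sodium_molar)
            + params.tm_gc_coeff * (100.0 * gc_fraction)
            - params.tm_length_coeff / length)


def _rng(params_seed: int, replicate_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((params_seed, replicate_seed)))


def helicity(amplicon: AmpliconRecord, params: MeltModelParams,
             temperatures: np.ndarray, tm_offset: float = 0.0) -> np.ndarray:
    """Fraction double-stranded at each temperature, in [0, 1]."""
    theta = np.zeros_like(temperatures, dtype=float)
    for _, gc, weight in domain_decompose(amplicon, params.n_domains):
        seg_len = weight * len(amplicon)
        tm = predict_domain_tm(gc, seg_len, params) + tm_offset
        theta += weight / (1.0 + np.exp(-(tm - temperatures) / params.transition_width))
    return theta


def simulate_melt(amplicon: AmpliconRecord, params: MeltModelParams,
                  grid: TemperatureGrid = TemperatureGrid(),
                  replicate_seed: int = 0,
                  run_id: str | None = None) -> MeltRun:
    """Simulate one melt-stage fluorescence series for an amplicon.

    All stochastic draws (amplitude jitter, per-run Tm offset, additive noise)
    come from a single generator seeded by ``(params.seed, replicate_seed)``,
    so identical seeds reproduce the run byte for byte.
    """
    rng = _rng(params.seed, replicate_seed)
    amplitude = rng.normal(1.0, params.amplitude_jitter_sd) if params.amplitude_jitter_sd > 0 else 1.0
    amplitude = max(amplitude, 0.05)
    tm_offset = rng.normal(0.0, params.tm_jitter_sd) if params.tm_jitter_sd > 0 else 0.0

    temps = grid.temperatures
    theta = helicity(amplicon, params, temps, tm_offset)
    ds = params.ds_baseline[0] + params.ds_baseline[1] * (temps - grid.start)
    ss = params.ss_baseline[0] + params.ss_baseline[1] * (temps - grid.start)
    signal = amplitude * (ds * theta + ss * (1.0 - theta))
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=temps.shape)

    return MeltRun(
        run_id=run_id or f"{amplicon.id}#r{replicate_seed}",
        stage="melt",
        x=temps,
        fluorescence=signal,
        species_label=amplicon.species_label or amplicon.id,
        metadata={
            "simulator": "meltid.meltsim",
            "params_seed": params.seed,
            "replicate_seed": replicate_seed,
            "amplitude": amplitude,
            "tm_offset": tm_offset,
        },
    )


def simulate_amplification(params: AmplificationParams,
                           run_id: str = "amp") -> MeltRun:
    """Simulate an amplification-stage fluorescence series (x = cycle index).

    Copy number grows geometrically and saturates at ``plateau_cap``;
    fluorescence maps copies linearly onto ``plateau_nfu`` above baseline.
    """
    rng = np.random.default_rng(params.seed)
    cycles = np.arange(1, params.cycles + 1, dtype=float)
    copies = np.minimum(
        params.initial_copies * (1.0 + params.efficiency) ** cycles,
        params.plateau_cap,
    )
    # scale chosen so the noiseless plateau-minus-baseline signal (mean of the
    # last 3 cycles minus mean of cycles 1-5) equals plateau_nfu exactly
    span = float(copies[-3:].mean() - copies[:5].mean())
    k = params.plateau_nfu / span if span > 0 else 0.0
    signal = params.baseline_rfu + k * copies
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=cycles.shape)
    return MeltRun(
        run_id=run_id,
        stage="amplification",
        x=cycles,
        fluorescence=signal,
        metadata={"simulator": "meltid.meltsim", "seed": params.seed,
                  "plateau_nfu": params.plateau_nfu},
    )


# Plateau strengths for normal vs weak (sub-LOI) reactions, in NFU.
STRONG_PLATEAU_NFU = 15.0
WEAK_PLATEAU_NFU = 4.0


def _weak_flags(n_total: int, weak_fraction: float) -> list[bool]:
    """Deterministic sub-LOI assignment: exactly floor(n * fraction) weak runs,
    spread evenly over the run index order."""
    flags = []
    acc_prev = 0
    for i in range(1, n_total + 1):
        acc = math.floor(i * weak_fraction + 1e-9)
        flags.append(acc > acc_prev)
        acc_prev = acc
    return flags


def make_labeled_dataset(fasta: str | Path | Sequence[AmpliconRecord],
                         n_per_species: int,
                         params: MeltModelParams = MeltModelParams(),
                         grid: TemperatureGrid = TemperatureGrid(),
                         master_seed: int = 0,
                         weak_fraction: float = 0.0,
                         ) -> tuple[list[MeltRun], pd.DataFrame]:
    """Simulate a labelled corpus: melt + amplification series per replicate.

    Each species in the FASTA gets ``n_per_species`` replicate runs with
    distinct replicate seeds derived from ``master_seed``.  A ``weak_fraction``
    of runs (assigned deterministically by run index, never by chance) is given
    sub-LOI amplification strength so downstream validity filtering has work
    to do.  Returns the runs plus a manifest DataFrame with columns
    run_id, species, seed, weak, plateau_nfu.
    """
    if isinstance(fasta, (str, Path)):
        records = read_fasta(fasta)
    else:
        records = list(fasta)
    by_label: dict[str, AmpliconRecord] = {}
    for rec in records:
        label = rec.species_label or rec.id
        if label in by_label and by_label[label].sequence != rec.sequence:
            raise ValueError(f"duplicate species label {label!r} with conflicting sequences")
        by_label.setdefault(label, rec)
    if len(by_label) < 2:
        raise ValueError("dataset needs at least 2 species")
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")

    n_total = len(by_label) * n_per_species
    weak = _weak_flags(n_total, weak_fraction)

    sim_params = dataclasses.replace(params, seed=master_seed)
    runs: list[MeltRun] = []
    rows = []
    idx = 0
    for label, rec in by_label.items():
        for rep in range(n_per_species):
            replicate_seed = idx + 1
            run_id = f"run{idx:04d}"
            melt = simulate_melt(rec, sim_params, grid,
                                 replicate_seed=replicate_seed, run_id=run_id)
            plateau = WEAK_PLATEAU_NFU if weak[idx] else STRONG_PLATEAU_NFU
            amp = simulate_amplification(
                AmplificationParams(plateau_nfu=plateau, noise_sd=0.2,
                                    seed=(master_seed * 100003 + replicate_seed) % (2**31)),
                run_id=run_id,
            )
            amp.species_label = label
            runs.extend([melt, amp])
            rows.append({"run_id": run_id, "species": label,
                         "seed": replicate_seed, "weak": bool(weak[idx]),
                         "plateau_nfu": plateau})
            idx += 1
    manifest = pd.DataFrame(rows)
    return runs, manifest


def write_runs_csv(runs: Sequence[MeltRun], path: str | Path) -> None:
    """Write runs in long format (run_id, species, stage, x, fluorescence)."""
    frames = []
    for run in runs:
        frames.append(pd.DataFrame({
            "run_id": run.run_id,
            "species": run.species_label,
            "stage": run.stage,
            "x": run.x,
            "fluorescence": run.fluorescence,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_runs_csv(path: str | Path,
                  column_map: dict[str, str] | None = None) -> list[MeltRun]:
    """Read long-format run CSV back into :class:`MeltRun` objects.

    ``column_map`` adapts instrument exports with different header names,
    e.g. ``{"run_id": "Well", "x": "Temperature", "fluorescence": "RFU"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = {"run_id", "stage", "x", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"run CSV missing columns {sorted(missing)}")
    runs = []
    for (run_id, stage), grp in df.groupby(["run_id", "stage"], sort=False):
        grp = grp.sort_values("x")
        species = ""
        if "species" in grp.columns and grp["species"].notna().any():
            species = str(grp["species"].iloc[0])
        runs.append(MeltRun(run_id=str(run_id), stage=str(stage),
                            x=grp["x"].to_numpy(),
                            fluorescence=grp["fluorescence"].to_numpy(),
                            species_label=species))
    return runs


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(orient="records"), indent=1))


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))
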