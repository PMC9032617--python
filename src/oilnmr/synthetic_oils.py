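"""Synthetic CPMG decays for pure and adulterated edible oils.

Transverse (T2) relaxation of vegetable oils at low field is well described
by a small number of relaxation populations: a fast minor component around
2-3 ms and two slower components near 65-75 ms and 210-250 ms that carry
most of the signal. Adulterating avocado oil (AO) with soybean (SO), corn
(CO) or rapeseed oil (RO) shifts the slow components to longer T2 and moves
area from the second to the third population, monotonically in the mass
fraction of adulterant. The generator in this module reproduces exactly that
structure: tri-component oil specs, mass-weighted mixing of noiseless
decays, multiplicative brand/replicate variability and additive Gaussian
noise, all reproducible from a single master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionSettings",
    "OilSpec",
    "MixtureSpec",
    "AdulterationRecord",
    "CPMGDecay",
    "StudyDesign",
    "DEFAULT_LEVELS",
    "default_oil_library",
    "mix_specs",
    "noiseless_amplitudes",
    "simulate_cpmg",
    "generate_study_dataset",
    "split_calibration_validation",
    "write_decays",
    "read_decays",
]

#: Mass fractions used in the default adulteration design (0 = pure base oil,
#: 1 = pure adulterant).
DEFAULT_LEVELS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0)

#: Levels at which mixtures are actually prepared (the interior of the design).
MIXTURE_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class AcquisitionSettings:
    """CPMG acquisition metadata.

    echo_spacing is the full echo time in ms (twice the 90-180 pulse gap);
    the sampled time axis is ``t_k = k * echo_spacing`` for k = 1..n_echoes.
    """

    echo_spacing: float = 0.2
    n_echoes: int = 8000
    n_scans: int = 8
    temperature_C: float = 32.0

    def __post_init__(self) -> None:
        if self.echo_spacing <= 0:
            raise ValueError("echo_spacing must be positive")
        if self.n_echoes < 2:
            raise ValueError("n_echoes must be at least 2")

    @property
    def times(self) -> np.ndarray:
        """Echo times in ms (1-based: the first echo is at one echo spacing)."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1, dtype=float)


@dataclass(frozen=True)
class OilSpec:
    """Tri-component T2 description of one oil.

    component_T2 are the three population centres in ms (strictly increasing);
    component_fraction their fractional areas (sum to 1); log_width the
    log-normal spread of each population on the ln-T2 axis, a scalar applied
    to all three or one value per component (0 gives discrete exponentials);
    specific_amplitude the signal per unit mass.
    """

    name: str
    component_T2: tuple[float, float, float]
    component_fraction: tuple[float, float, float]
    log_width: float | tuple[float, float, float] = 0.08
    specific_amplitude: float = 1.0

    def __post_init__(self) -> None:
        t2 = np.asarray(self.component_T2, dtype=float)
        fr = np.asarray(self.component_fraction, dtype=float)
        if t2.shape != (3,) or fr.shape != (3,):
            raise ValueError("component_T2 and component_fraction must have length 3")
        if not np.all(np.diff(t2) > 0):
            raise ValueError("component_T2 must be strictly increasing")
        if np.any(fr <= 0) or np.any(fr >= 1):
            raise ValueError("component fractions must lie in (0, 1)")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if np.any(np.asarray(self.log_width) < 0):
            raise ValueError("log_width must be non-negative")

    @property
    def component_log_width(self) -> np.ndarray:
        """Per-component ln-T2 spreads (scalar broadcast to all three)."""
        return np.broadcast_to(np.asarray(self.log_width, dtype=float), (3,))


@dataclass(frozen=True)
class MixtureSpec:
    """Mass-fraction blend of two oil specs.

    The noiseless mixture decay is the mass-weighted sum of the pure decays,
    each scaled by its specific amplitude; no interaction term is modelled
    (proton signals of triglyceride blends add linearly).
    """

    base: OilSpec
    adulterant: OilSpec
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"mixture level must be in [0, 1], got {self.level}")


@dataclass(frozen=True)
class AdulterationRecord:
    """Ground truth attached to one synthetic sample."""

    base: str
    adulterant: str | None
    level: float
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        if (self.adulterant is None) != (self.level == 0.0):
            raise ValueError("level must be 0 exactly when there is no adulterant")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must be a mass fraction in [0, 1]")

    @property
    def label(self) -> str:
        """Series label: AO for pure avocado, AO-<X> for blends, <X> for pure adulterant."""
        if self.adulterant is None:
            return "AO"
        if self.level == 1.0:
            return self.adulterant
        return f"AO-{self.adulterant}"

    @property
    def sample_id(self) -> str:
        adt = self.adulterant or "none"
        return f"{self.base}_{adt}_{self.level:g}_r{self.replicate}"


@dataclass(frozen=True, eq=False)
class CPMGDecay:
    """A sampled CPMG echo-train decay with its acquisition and ground truth."""

    times: np.ndarray
    amplitudes: np.ndarray
    settings: AcquisitionSettings
    record: AdulterationRecord | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be 1-D arrays of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)


# ---------------------------------------------------------------------------
# Oil library
# ---------------------------------------------------------------------------

# Base avocado-oil spec; per-brand variability is applied as fixed offsets
# (within +/-2 % on T2 centres and +/-0.5 percentage points on proportions).
_AO_BASE_T2 = (3.00, 67.5, 218.0)
_AO_BASE_FRACTION = (0.023, 0.611, 0.366)

_BRAND_T2_FACTORS = {
    "AO-1": (1.000, 1.000, 1.000),
    "AO-2": (0.985, 1.012, 0.990),
    "AO-3": (1.018, 0.990, 1.010),
    "AO-4": (1.008, 1.005, 0.982),
}
_BRAND_FRACTION_OFFSETS = {  # percentage points, sum to zero per brand
    "AO-1": (0.0, 0.0, 0.0),
    "AO-2": (0.2, -0.5, 0.3),
    "AO-3": (-0.3, 0.5, -0.2),
    "AO-4": (0.1, -0.3, 0.2),
}


def default_oil_library() -> dict[str, OilSpec]:
    """Specs for four avocado-oil brands and the three adulterants.

    Pure-oil proportions follow the endpoints of the adulteration series:
    avocado near (2.3, 61.1, 36.6) %, soybean (1.8, 55.5, 42.7) %, corn
    (1.9, 55.1, 43.0) %. Rapeseed sits within the avocado T2 bands
    (centres 5-8 % above avocado, P22 about 1.5 points lower) so that
    rapeseed blends overlap avocado oil in feature space, which is the hard
    case for classification.

    Each oil also carries its own component line width and specific
    amplitude: PUFA-rich oils have broader T2 populations (more
    heterogeneous triglyceride environments) and a slightly lower proton
    density per gram than MUFA-rich avocado oil, so the component start/end
    times and the total signal area are oil-specific features and not just
    rescaled copies of the avocado values.
    """
    library: dict[str, OilSpec] = {}
    for brand, factors in _BRAND_T2_FACTORS.items():
        t2 = tuple(c * f for c, f in zip(_AO_BASE_T2, factors))
        off = _BRAND_FRACTION_OFFSETS[brand]
        fr = np.asarray(_AO_BASE_FRACTION) + np.asarray(off) / 100.0
        fr = fr / fr.sum()
        library[brand] = OilSpec(brand, t2, tuple(fr), log_width=(0.05, 0.07, 0.07))
    library["SO"] = OilSpec("SO", (2.13, 72.7, 252.0), (0.018, 0.555, 0.427),
                            log_width=(0.06, 0.10, 0.14), specific_amplitude=0.970)
    library["CO"] = OilSpec("CO", (2.40, 71.3, 243.7), (0.019, 0.551, 0.430),
                            log_width=(0.09, 0.15, 0.09), specific_amplitude=0.982)
    library["RO"] = OilSpec("RO", (3.15, 71.0, 230.0), (0.024, 0.596, 0.380),
                            log_width=(0.05, 0.09, 0.12), specific_amplitude=0.995)
    return library


# ---------------------------------------------------------------------------
# Decay synthesis
# ---------------------------------------------------------------------------

def mix_specs(base: OilSpec, adulterant: OilSpec, level: float) -> MixtureSpec:
    """Blend ``level`` mass fraction of adulterant into the base oil."""
    return MixtureSpec(base=base, adulterant=adulterant, level=level)


def _spec_amplitudes(spec: OilSpec, times: np.ndarray) -> np.ndarray:
    """Noiseless decay of a pure oil, amplitude spec.specific_amplitude at t=0.

    Each component is spread log-normally (sd ``log_width`` on ln T2) over a
    33-point quadrature sub-grid; log_width = 0 collapses to a discrete
    tri-exponential.
    """
    t = np.asarray(times, dtype=float)
    total = np.zeros_like(t)
    fractions = np.asarray(spec.component_fraction)
    widths = spec.component_log_width
    for t2c, frac, width in zip(spec.component_T2, fractions, widths):
        if width == 0:
            total += frac * np.exp(-t / t2c)
        else:
            u = np.linspace(-4.0, 4.0, 33)
            w = np.exp(-0.5 * u**2)
            w /= w.sum()
            t2s = t2c * np.exp(width * u)
            total += frac * np.exp(-t[:, None] / t2s[None, :]) @ w
    return spec.specific_amplitude * total


def noiseless_amplitudes(spec: OilSpec | MixtureSpec, times: np.ndarray) -> np.ndarray:
    """Noise-free CPMG amplitude at the given times (ms)."""
    if isinstance(spec, MixtureSpec):
        base = _spec_amplitudes(spec.base, times)
        adt = _spec_amplitudes(spec.adulterant, times)
        return (1.0 - spec.level) * base + spec.level * adt
    return _spec_amplitudes(spec, times)


def simulate_cpmg(
    spec: OilSpec | MixtureSpec,
    settings: AcquisitionSettings | None = None,
    snr: float = 2000.0,
    seed: int = 0,
    record: AdulterationRecord | None = None,
) -> CPMGDecay:
    """Simulate one CPMG acquisition.

    Additive Gaussian noise with standard deviation a(0)/snr, where a(0) is
    the noiseless amplitude extrapolated to t=0. The same seed always yields
    bit-identical output.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    settings = settings or AcquisitionSettings()
    times = settings.times
    clean = noiseless_amplitudes(spec, times)
    a0 = float(noiseless_amplitudes(spec, np.array([0.0]))[0])
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, a0 / snr, size=times.shape)
    return CPMGDecay(times=times, amplitudes=noisy, settings=settings, record=record)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Counts and conditions of the synthetic adulteration study.

    The default reproduces the benchmark design: 4 avocado brands x 5
    replicates, one brand each of soybean/corn/rapeseed x 5 replicates
    (represented as level-1.0 members of their series), and for each
    adulterant 6 interior levels (10-80 %) x 10 replicates: 215 decays.
    Replicate variability is a multiplicative log-normal jitter on the T2
    centres (sd ``t2_jitter`` on the ln scale) plus an additive Gaussian
    perturbation of the component proportions (sd ``fraction_jitter``
    percentage points, renormalised).
    """

    ao_brands: tuple[str, ...] = ("AO-1", "AO-2", "AO-3", "AO-4")
    adulterants: tuple[str, ...] = ("SO", "CO", "RO")
    pure_ao_replicates: int = 5
    pure_adulterant_replicates: int = 5
    mixture_levels: tuple[float, ...] = MIXTURE_LEVELS
    mixture_replicates: int = 10
    snr: float = 2000.0
    t2_jitter: float = 0.002
    fraction_jitter: float = 0.15

    @property
    def n_samples(self) -> int:
        return (
            len(self.ao_brands) * self.pure_ao_replicates
            + len(self.adulterants) * self.pure_adulterant_replicates
            + len(self.adulterants) * len(self.mixture_levels) * self.mixture_replicates
        )


def _sample_seed(master_seed: int, base: str, adulterant: str | None, level: float, replicate: int) -> int:
    """Stable per-sample seed: CRC of the sample identity mixed with the master seed."""
    key = f"{base}|{adulterant or 'none'}|{level:.6f}|{replicate}"
    crc = zlib.crc32(key.encode())
    ss = np.random.SeedSequence([int(master_seed), crc])
    return int(ss.generate_state(1)[0] % (2**31))


def _jitter_spec(spec: OilSpec, rng: np.random.Generator, t2_sigma: float, frac_sigma_points: float) -> OilSpec:
    """Replicate-level variability: log-normal T2 jitter, Gaussian proportion jitter."""
    t2 = np.asarray(spec.component_T2) * np.exp(rng.normal(0.0, t2_sigma, 3))
    fr = np.asarray(spec.component_fraction) + rng.normal(0.0, frac_sigma_points / 100.0, 3)
    fr = np.clip(fr, 1e-4, None)
    fr = fr / fr.sum()
    return replace(spec, component_T2=tuple(t2), component_fraction=tuple(fr))


def generate_study_dataset(
    design: StudyDesign | None = None,
    seed: int = 0,
    library: Mapping[str, OilSpec] | None = None,
    settings: AcquisitionSettings | None = None,
) -> list[CPMGDecay]:
    """Simulate the full adulteration study.

    Every decay carries an :class:`AdulterationRecord` with the true mass
    fraction. Per-sample seeds are derived by stable hashing of
    (group, level, replicate) mixed with the master seed, so any subset of
    the design is reproducible independently of generation order.
    """
    design = design or StudyDesign()
    library = dict(library or default_oil_library())
    settings = settings or AcquisitionSettings()
    decays: list[CPMGDecay] = []

    def build(base_name: str, adulterant: str | None, level: float, replicate: int) -> CPMGDecay:
        s = _sample_seed(seed, base_name, adulterant, level, replicate)
        rng = np.random.default_rng(np.random.SeedSequence([s, 1]))
        base_spec = _jitter_spec(library[base_name], rng, design.t2_jitter, design.fraction_jitter)
        if adulterant is None:
            spec: OilSpec | MixtureSpec = base_spec
        else:
            adt_spec = _jitter_spec(library[adulterant], rng, design.t2_jitter, design.fraction_jitter)
            spec = mix_specs(base_spec, adt_spec, level)
        record = AdulterationRecord(base=base_name, adulterant=adulterant, level=level, replicate=replicate, seed=s)
        return simulate_cpmg(spec, settings, snr=design.snr, seed=s, record=record)

    for brand in design.ao_brands:
        for rep in range(design.pure_ao_replicates):
            decays.append(build(brand, None, 0.0, rep))

    # The base brand for each mixture (and for the pure-adulterant bottles,
    # which enter the series at level 1.0) is drawn at random from the four
    # avocado brands, as in the benchmark protocol.
    brand_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB24]))
    for adt in design.adulterants:
        for rep in range(design.pure_adulterant_replicates):
            brand = design.ao_brands[brand_rng.integers(len(design.ao_brands))]
            decays.append(build(brand, adt, 1.0, rep))
        for level in design.mixture_levels:
            for rep in range(design.mixture_replicates):
                brand = design.ao_brands[brand_rng.integers(len(design.ao_brands))]
                decays.append(build(brand, adt, level, rep))
    return decays


def split_calibration_validation(
    dataset: Sequence[CPMGDecay],
    calibration_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    levels: Iterable[float] | None = None,
) -> tuple[list[CPMGDecay], list[CPMGDecay]]:
    """Stratified random split into calibration and validation sets.

    ``calibration_counts`` maps a series label (``AO``, ``AO-SO``, ...) to the
    number of calibration samples for that group; the remainder of the group
    goes to validation. Within adulterated groups the draw is stratified by
    level so every level contributes proportionally. Samples whose label is
    not in the mapping are excluded from both sets. The default reproduces
    the benchmark classification split: 15+42+42+42 calibration and
    5+18+18+18 validation over levels 10-80 %.
    """
    if calibration_counts is None:
        calibration_counts = {"AO": 15, "AO-SO": 42, "AO-CO": 42, "AO-RO": 42}
        if levels is None:
            levels = MIXTURE_LEVELS
    rng = np.random.default_rng(seed)
    level_set = None if levels is None else {round(float(l), 6) for l in levels} | {0.0}

    groups: dict[str, list[CPMGDecay]] = {}
    for d in dataset:
        if d.record is None:
            raise ValueError("split requires decays with adulteration records")
        if level_set is not None and round(d.record.level, 6) not in level_set:
            continue
        groups.setdefault(d.record.label, []).append(d)

    calibration: list[CPMGDecay] = []
    validation: list[CPMGDecay] = []
    for label in sorted(calibration_counts):
        want = calibration_counts[label]
        members = groups.get(label, [])
        if want > len(members):
            raise ValueError(
                f"group {label!r} has only {len(members)} samples, "
                f"cannot place {want} in calibration"
            )
        # stratify by level within the group
        by_level: dict[float, list[CPMGDecay]] = {}
        for d in members:
            by_level.setdefault(round(d.record.level, 6), []).append(d)
        n_levels = len(by_level)
        base_take, extra = divmod(want, n_levels)
        level_keys = sorted(by_level)
        # distribute the remainder over a seeded shuffle of the levels
        order = list(rng.permutation(n_levels))
        takes = {level_keys[i]: base_take + (1 if rank < extra else 0)
                 for rank, i in enumerate(order)}
        for lv in level_keys:
            pool = by_level[lv]
            take = min(takes[lv], len(pool))
            idx = rng.permutation(len(pool))
            chosen = set(idx[:take])
            for i, d in enumerate(pool):
                (calibration if i in chosen else validation).append(d)
            takes[lv] = take
        short = want - sum(takes.values())
        if short:  # uneven level pools: top up from validation members of the group
            movable = [d for d in validation if d.record.label == label]
            idx = rng.permutation(len(movable))[:short]
            for i in idx:
                calibration.append(movable[i])
                validation.remove(movable[i])
    return calibration, validation


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_decays(decays: Sequence[CPMGDecay], outdir: str | Path) -> Path:
    """Write one ``time_ms,amplitude`` CSV per decay plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in decays:
        rec = d.record
        if rec is None:
            raise ValueError("cannot write a decay without a record")
        fname = f"{rec.sample_id}.csv"
        pd.DataFrame({"time_ms": d.times, "amplitude": d.amplitudes}).to_csv(
            outdir / fname, index=False, float_format="%.17g")  # exact round trip
        rows.append({
            "sample_id": rec.sample_id, "base": rec.base,
            "adulterant": rec.adulterant or "", "level": rec.level,
            "replicate": rec.replicate, "seed": rec.seed, "file": fname,
            "echo_spacing": d.settings.echo_spacing, "n_echoes": d.settings.n_echoes,
            "n_scans": d.settings.n_scans, "temperature_C": d.settings.temperature_C,
        })
    meta = outdir / "samples.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    return meta


def read_decays(metadata_csv: str | Path) -> list[CPMGDecay]:
    """Load decays written by :func:`write_decays`."""
    meta_path = Path(metadata_csv)
    meta = pd.read_csv(meta_path, keep_default_na=False)
    decays = []
    for _, row in meta.iterrows():
        table = pd.read_csv(meta_path.parent / row["file"], float_precision="round_trip")
        settings = AcquisitionSettings(
            echo_spacing=float(row["echo_spacing"]), n_echoes=int(row["n_echoes"]),
            n_scans=int(row["n_scans"]), temperature_C=float(row["temperature_C"]),
        )
        record = AdulterationRecord(
            base=str(row["base"]),
            adulterant=(str(row["adulterant"]) or None),
            level=float(row["level"]), replicate=int(row["replicate"]), seed=int(row["seed"]),
        )
        decays.append(CPMGDecay(
            times=table["time_ms"].to_numpy(), amplitudes=table["amplitude"].to_numpy(),
            settings=settings, record=record,
        ))
    return decays
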