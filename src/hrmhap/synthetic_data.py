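"""Simulate melt curves and population screens from haplotype sequences.

Real HRM data come off an instrument; this module generates equivalent
plate runs directly from sequence differences so that every pipeline stage
is testable without a thermocycler.  The physical model is deliberately
simple and explicit:

* The base amplicon melt temperature follows the empirical GC/length form
  Tm = 81.5 + 0.41 * %GC - 675 / length.
* Each nucleotide substitution relative to a designated reference haplotype
  shifts Tm by a class-dependent amount: transitions (class 1) shift most,
  C<->A / G<->T transversions (class 2) less, and the GC-neutral C<->G
  (class 3) and A<->T (class 4) swaps barely at all - matching the
  well-known ranking of SNP detectability by melt analysis.  The shift sign
  follows the GC change of the derived base.  Indels shift Tm per gap base.
* A melt curve is a two-state sigmoid in temperature riding on a linear
  drift, with Gaussian fluorescence noise and per-well Tm jitter;
  amplification curves are logistic in cycle number.  Designated failure
  wells produce flat amplification and a melt curve without a transition.

Multi-SNP effects are additive by default; an optional cancellation mode
halves the net shift of multi-difference pairs to emulate substitutions
counteracting one another.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .haplotyping import GAP, HaplotypeSet
from .melt_model import (
    AmplificationCurve,
    MeltCurve,
    PlateRecord,
    Well,
)

__all__ = [
    "SnpClassModel",
    "SimConfig",
    "predict_tm",
    "snp_class",
    "tm_offset",
    "simulate_melt",
    "simulate_haplotype_trial",
    "simulate_population_screen",
]

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True)
class SnpClassModel:
    """Per-SNP-class mean delta-Tm magnitudes (degC) and indel effect.

    Defaults encode the qualitative ranking class1 > class2 > class3 ~
    class4 (transitions change GC content and stacking most; C<->G and
    A<->T are GC-neutral).  They are simulator parameters, not measured
    instrument values.
    """

    class1: float = 0.50
    class2: float = 0.25
    class3: float = 0.05
    class4: float = 0.05
    indel_per_bp: float = 0.06
    shape_distortion: float = 0.0
    cancellation: bool = False

    def __post_init__(self) -> None:
        if min(self.class1, self.class2, self.class3, self.class4, self.indel_per_bp) < 0:
            raise ValueError("delta-Tm magnitudes must be >= 0")
        if not (self.class1 >= self.class2 >= self.class3 and self.class2 >= self.class4):
            raise ValueError("defaults require class1 >= class2 >= class3, class4")

    def magnitude(self, cls: int) -> float:
        return (self.class1, self.class2, self.class3, self.class4)[cls - 1]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for simulated runs.

    Noise defaults emulate a well-calibrated high-precision melt plate:
    0.004 degC well-to-well Tm jitter and 0.1% of the melt amplitude as
    fluorescence noise.  The instrument convention of a 0.05 degC delta-Tm
    clustering threshold presupposes per-well melt-peak reproducibility of
    roughly 0.01 degC, which these defaults (plus the Tm caller's
    estimation error) realize.

    ``base_tm_shift`` recenters amplicon melt peaks: the empirical GC/length
    Tm form overestimates dye-saturated melt peaks for AT-rich chloroplast
    amplicons, and real assay design places the transition mid-sweep so the
    post-melt baseline is flat; the default -4 degC does the same here.
    """

    seed: int = 0
    replicates_per_haplotype: int = 16
    fluorescence_noise_sd: float = 0.001
    tm_jitter_sd: float = 0.004
    amplification_failure_rate: float = 0.0
    duplicate_split_rate: float = 0.0
    split_shift: float = 0.12
    melt_width: float = 0.7
    amplitude: float = 1.0
    drift_intercept: float = 0.05
    drift_slope: float = -0.002
    base_tm_shift: float = -4.0
    amp_plateau: float = 1000.0
    amp_baseline: float = 20.0
    temp_start: float = 65.0
    temp_stop: float = 95.0
    temp_step: float = 0.2
    n_cycles: int = 40

    def __post_init__(self) -> None:
        for p in (self.amplification_failure_rate, self.duplicate_split_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities in [0, 1]")
        if min(self.fluorescence_noise_sd, self.tm_jitter_sd) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def temperatures(self) -> np.ndarray:
        n = int(round((self.temp_stop - self.temp_start) / self.temp_step)) + 1
        return self.temp_start + self.temp_step * np.arange(n)


def predict_tm(sequence: str) -> float:
    """Empirical amplicon melt temperature from GC fraction and length."""
    seq = sequence.upper().replace(GAP, "")
    if len(seq) < 50:
        raise ValueError("sequence must be at least 50 bp")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
    return 81.5 + 0.41 * gc - 675.0 / len(seq)


def snp_class(a: str, b: str) -> int:
    """SNP class of a substitution: 1 transition, 2 C<->A/G<->T, 3 C<->G, 4 A<->T."""
    pair = {a.upper(), b.upper()}
    if len(pair) != 2 or not pair <= set("ACGT"):
        raise ValueError(f"not a substitution: {a!r} -> {b!r}")
    if pair in _TRANSITIONS:
        return 1
    if pair == {"C", "G"}:
        return 3
    if pair == {"A", "T"}:
        return 4
    return 2


def _gc_sign(ref_base: str, alt_base: str) -> float:
    gc = {"G", "C"}
    if alt_base in gc and ref_base not in gc:
        return 1.0
    if ref_base in gc and alt_base not in gc:
        return -1.0
    return 1.0  # GC-neutral swap: tiny magnitude, sign immaterial


def tm_offset(reference: str, variant: str, model: SnpClassModel) -> float:
    """Net delta-Tm of an aligned variant relative to the reference.

    Substitution columns contribute signed class magnitudes; each maximal
    gap run contributes indel_per_bp * run_length, negative for deletions
    (gap in the variant) and positive for insertions.
    """
    if len(reference) != len(variant):
        raise ValueError("reference and variant must be aligned (equal length)")
    total = 0.0
    n_events = 0
    col = 0
    length = len(reference)
    while col < length:
        r, v = reference[col].upper(), variant[col].upper()
        if r == v or (r == GAP and v == GAP):
            col += 1
            continue
        if r == GAP or v == GAP:
            gap_in_variant = v == GAP
            sign = -1.0 if gap_in_variant else 1.0

            def in_run(i: int) -> bool:
                return (variant[i] == GAP) == gap_in_variant and (
                    (reference[i] == GAP) != gap_in_variant
                )

            run = col
            while run < length and in_run(run):
                run += 1
            total += sign * model.indel_per_bp * (run - col)
            n_events += 1
            col = run
        else:
            total += _gc_sign(r, v) * model.magnitude(snp_class(r, v))
            n_events += 1
            col += 1
    if model.cancellation and n_events > 1:
        total *= 0.5
    return total


# ---------------------------------------------------------------------------
# curve synthesis
# ---------------------------------------------------------------------------

def _melt_curve(tm: float, config: SimConfig, rng: np.random.Generator, melted: bool = False) -> MeltCurve:
    t = config.temperatures()
    drift = config.drift_intercept + config.drift_slope * (t - t[0])
    if melted:
        signal = np.zeros_like(t)
    else:
        signal = config.amplitude / (1.0 + np.exp((t - tm) / config.melt_width))
    noise = rng.normal(0.0, config.fluorescence_noise_sd, size=t.shape) \
        if config.fluorescence_noise_sd > 0 else 0.0
    return MeltCurve(t, drift + signal + noise)


def _amp_curve(config: SimConfig, rng: np.random.Generator, failed: bool) -> AmplificationCurve:
    cycles = np.arange(1, config.n_cycles + 1, dtype=float)
    plateau = config.amp_plateau * (0.02 if failed else 1.0)
    f = config.amp_baseline + plateau / (1.0 + np.exp(-(cycles - 22.0) / 2.5))
    if config.fluorescence_noise_sd > 0:
        f = f + rng.normal(0.0, config.fluorescence_noise_sd * config.amp_plateau * 0.002,
                           size=f.shape)
    return AmplificationCurve(cycles, f)


def simulate_melt(
    haplotype: str,
    model: SnpClassModel,
    config: SimConfig,
    reference: str | None = None,
    rng: np.random.Generator | None = None,
    failed: bool = False,
) -> tuple[MeltCurve, AmplificationCurve, dict]:
    """One well's melt + amplification curves with its truth record.

    ``haplotype`` is the (possibly gapped) aligned sequence; ``reference``
    defaults to the haplotype itself (zero offset).  The truth record
    carries the exact per-well Tm and the offset applied.
    """
    rng = rng or np.random.default_rng(config.seed)
    ref = reference if reference is not None else haplotype
    base = predict_tm(ref) + config.base_tm_shift
    offset = tm_offset(ref, haplotype, model) if reference is not None else 0.0
    jitter = float(rng.normal(0.0, config.tm_jitter_sd)) if config.tm_jitter_sd > 0 else 0.0
    tm = base + offset + jitter
    melt = _melt_curve(tm, config, rng, melted=failed)
    amp = _amp_curve(config, rng, failed)
    truth = {"tm": tm, "tm_offset": offset, "base_tm": base, "failed": failed}
    return melt, amp, truth


def _well_ids() -> Iterable[tuple[str, str]]:
    plate = 1
    while True:
        for row in string.ascii_uppercase[:8]:
            for col in range(1, 13):
                yield f"P{plate}", f"{row}{col}"
        plate += 1


def simulate_haplotype_trial(
    sequences: Mapping[str, str],
    model: SnpClassModel,
    config: SimConfig,
    reference_label: str | None = None,
    failed_wells: Mapping[str, Sequence[int]] | None = None,
) -> tuple[list[PlateRecord], dict]:
    """Replicated known-haplotype run (the discrimination-trial design).

    Each haplotype is amplified ``config.replicates_per_haplotype`` times.
    ``failed_wells`` designates replicate indices (per haplotype label) that
    fail amplification; additionally each well fails independently with
    ``config.amplification_failure_rate``.  Returns plate records plus a
    truth map: well key -> {haplotype, tm, failed}.
    """
    rng = np.random.default_rng(config.seed)
    reference_label = reference_label or sorted(sequences)[0]
    ref = sequences[reference_label]
    records: list[PlateRecord] = []
    truth: dict = {}
    ids = _well_ids()
    for hap in sorted(sequences):
        for rep in range(1, config.replicates_per_haplotype + 1):
            plate_id, well_id = next(ids)
            designated = rep in (failed_wells or {}).get(hap, ())
            random_fail = (
                config.amplification_failure_rate > 0
                and rng.random() < config.amplification_failure_rate
            )
            failed = designated or random_fail
            melt, amp, rec = simulate_melt(
                sequences[hap], model, config, reference=ref, rng=rng, failed=failed
            )
            well = Well(plate_id, well_id, sample_id=f"{hap}-r{rep}",
                        replicate_index=rep, known_haplotype=hap)
            records.append(PlateRecord(well=well, amplification=amp, melt=melt))
            truth[well.key] = {"haplotype": hap, **rec}
    return records, truth


def simulate_population_screen(
    table,
    haplotypes: HaplotypeSet,
    model: SnpClassModel,
    config: SimConfig,
    reference_label: str | None = None,
) -> tuple[list[PlateRecord], dict]:
    """Simulate an HRM screen of wild populations for one locus.

    ``table`` is a PopulationTable; each accession runs in duplicate wells,
    grouped per population.  Truth haplotypes follow the table's exact
    counts (not resampled).  ``config.duplicate_split_rate`` injects
    split-duplicate artefacts: affected samples get one well's Tm shifted
    by ``config.split_shift`` so it forms its own cluster.  Returns plate
    records and a truth dict with per-sample haplotypes, per-well Tm and
    the set of injected split samples.
    """
    rng = np.random.default_rng(config.seed)
    if reference_label is None:
        reference_label = table.counts.sum(axis=0).idxmax()
    ref = haplotypes.sequences[reference_label]
    records: list[PlateRecord] = []
    sample_truth: dict[str, dict] = {}
    well_truth: dict = {}
    split_samples: list[str] = []
    ids = _well_ids()
    for pop in table.populations:
        counter = 0
        for hap in table.haplotypes:
            for _ in range(int(table.counts.loc[pop, hap])):
                counter += 1
                sample_id = f"{pop}-{counter:03d}"
                split = config.duplicate_split_rate > 0 and rng.random() < config.duplicate_split_rate
                if split:
                    split_samples.append(sample_id)
                wells = []
                for rep in (1, 2):
                    plate_id, well_id = next(ids)
                    melt, amp, rec = simulate_melt(
                        haplotypes.sequences[hap], model, config, reference=ref, rng=rng
                    )
                    if split and rep == 2:
                        shifted = rec["tm"] + config.split_shift
                        melt = _melt_curve(shifted, config, rng)
                        rec = {**rec, "tm": shifted, "split_injected": True}
                    well = Well(plate_id, well_id, sample_id=sample_id,
                                population_id=pop, replicate_index=rep, known_haplotype=hap)
                    records.append(PlateRecord(well=well, amplification=amp, melt=melt))
                    well_truth[well.key] = {"haplotype": hap, "sample": sample_id, **rec}
                    wells.append(well.key)
                sample_truth[sample_id] = {
                    "population": pop, "haplotype": hap, "wells": wells,
                    "split_injected": split,
                }
    truth = {
        "samples": sample_truth,
        "wells": well_truth,
        "split_samples": split_samples,
        "reference": reference_label,
    }
    return records, truth
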