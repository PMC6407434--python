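"""Synthetic cohorts for smMIP targeted RNA sequencing.

No public dataset accompanies the study design this package targets, so the
simulator stands in for patient material.  It emulates a capture panel of
~900 probes over ~150 transcripts, a cohort of patients contributing one
healthy tissue sample and several tumor biopsies each, tumor-specific
expression shifts (glycolysis up, TCA cycle down in the motivating
application), PCR duplication of captured molecules, uniform per-base
sequencing error, and heterozygous-level variants spiked only into tumor
samples.  Every random draw flows from a single seed, and the generator
records the full ground truth so downstream stages can be tested against
it.

Read layout (shared contract with :mod:`smmipseq.quantify`)::

    UMI (umi_length bases) | extension arm | gap fill | ligation arm
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDefinition, SmMIPProbe

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for unusable simulation configurations."""


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def make_random_panel(
    n_probes: int = 898,
    n_transcripts: int = 150,
    seed: int = 0,
    arm_length: int = 20,
    target_length: int = 100,
    umi_length: int = 8,
) -> PanelDefinition:
    """Build a random but structurally realistic capture panel.

    Probes are distributed round-robin over transcripts (every transcript
    gets at least one), and each probe's arms are the reference sequence
    immediately flanking its gap-fill window, so simulated reads are
    contiguous transcript sequence.
    """
    if n_probes < n_transcripts:
        raise SimulationError("need at least one probe per transcript")
    rng = np.random.default_rng(seed)
    per_transcript = np.full(n_transcripts, n_probes // n_transcripts)
    per_transcript[: n_probes % n_transcripts] += 1

    transcripts: dict[str, str] = {}
    probes: list[SmMIPProbe] = []
    for t_idx in range(n_transcripts):
        tid = f"TX{t_idx + 1:04d}"
        k = per_transcript[t_idx]
        # windows tile the transcript with arm-length gaps between them
        length = arm_length + k * (target_length + arm_length)
        seq = "".join(rng.choice(_BASES, size=length))
        transcripts[tid] = seq
        for j in range(k):
            start = arm_length + j * (target_length + arm_length)
            end = start + target_length
            probes.append(
                SmMIPProbe(
                    probe_id=f"{tid}_P{j + 1:02d}",
                    transcript_id=tid,
                    extension_arm=seq[start - arm_length : start],
                    ligation_arm=seq[end : end + arm_length],
                    umi_length=umi_length,
                    target_start=start,
                    target_end=end,
                    strand="+",
                )
            )
    return PanelDefinition(probes=probes, transcripts=transcripts)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikedVariant:
    """A variant injected at molecule level at a fixed allele fraction.

    ``ref`` and ``alt`` are anchored strings in transcript space
    (substitution: ref "T" / alt "C"; deletion: ref "TG" / alt "T";
    insertion: ref "T" / alt "TG").
    """

    transcript_id: str
    position: int
    ref: str
    alt: str
    vaf: float
    tumor_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 1:
            raise SimulationError(f"target VAF must be in (0, 1], got {self.vaf}")
        if self.ref == self.alt:
            raise SimulationError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.position, self.ref, self.alt)


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated cohort."""

    panel: PanelDefinition
    seed: int = 0
    n_patients: int = 5
    tumor_biopsies_per_patient: int = 3
    baseline_molecules_per_probe: float = 300.0
    effect_map: dict[str, float] = field(default_factory=dict)
    duplication_mean: float = 3.0
    error_rate: float = 0.001
    spiked_variants: list[SpikedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_molecules_per_probe < 0:
            raise SimulationError("baseline_molecules_per_probe must be >= 0")
        if self.duplication_mean < 1:
            raise SimulationError("duplication_mean must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must be in [0, 1)")
        for tid, fc in self.effect_map.items():
            if tid not in self.panel.transcripts:
                raise SimulationError(f"effect_map names unknown transcript {tid!r}")
            if abs(fc) < 1:
                raise SimulationError(
                    f"fold change for {tid!r} must satisfy |fc| >= 1 "
                    "(signed convention)"
                )
        for v in self.spiked_variants:
            self._check_observable(v)

    def _check_observable(self, v: SpikedVariant) -> None:
        ref_seq = self.panel.transcripts.get(v.transcript_id)
        if ref_seq is None:
            raise SimulationError(f"variant on unknown transcript {v.transcript_id!r}")
        span = (v.position, v.position + len(v.ref))
        if ref_seq[span[0] : span[1]] != v.ref:
            raise SimulationError(
                f"variant ref {v.ref!r} does not match transcript "
                f"{v.transcript_id!r} at {v.position}"
            )
        for probe in self.panel.probes_for_transcript(v.transcript_id):
            if probe.target_start <= span[0] and span[1] <= probe.target_end:
                return
        raise SimulationError(
            f"variant at {v.transcript_id}:{v.position} lies outside every "
            "probe target window and would be unobservable"
        )


def patient_ids(n_patients: int) -> list[str]:
    """Patient labels A, B, C, ... (AA, AB, ... past 26)."""
    letters = string.ascii_uppercase
    out = []
    for i in range(n_patients):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: sample_id, patient_id, tissue (healthy/tumor)."""
    rows = []
    for pat in patient_ids(config.n_patients):
        rows.append({"sample_id": f"{pat}_H", "patient_id": pat, "tissue": "healthy"})
        for t in range(1, config.tumor_biopsies_per_patient + 1):
            rows.append(
                {"sample_id": f"{pat}_T{t}", "patient_id": pat, "tissue": "tumor"}
            )
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    molecule_counts: pd.DataFrame  # probe x sample, true unique molecules
    variant_fractions: pd.DataFrame  # sample, variant key fields, realized fraction
    samples: pd.DataFrame  # sample sheet (sample_id, patient_id, tissue)

    def label(self, sample_id: str) -> str:
        row = self.samples.loc[self.samples.sample_id == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row.tissue.iloc[0]


def _effect_multiplier(fc: float) -> float:
    # signed fold-change convention: -k means a 1/k shift
    return fc if fc >= 1 else -1.0 / fc


def simulate_molecule_counts(config: SimulationConfig) -> GroundTruth:
    """Draw true unique-molecule counts per (probe, sample).

    Counts are Poisson with mean ``baseline × effect`` where the effect
    multiplier applies only in tumor samples and only for transcripts in
    the effect map.  This is the molecule layer that
    :func:`simulate_cohort` renders into reads; it can be used directly
    when read-level detail is not needed.
    """
    rng = np.random.default_rng(config.seed)
    sheet = sample_sheet(config)
    probe_ids = [p.probe_id for p in config.panel.probes]
    lam_base = np.array(
        [config.baseline_molecules_per_probe for _ in config.panel.probes]
    )
    mult = np.array(
        [
            _effect_multiplier(config.effect_map[p.transcript_id])
            if p.transcript_id in config.effect_map
            else 1.0
            for p in config.panel.probes
        ]
    )
    cols = {}
    for _, row in sheet.iterrows():
        lam = lam_base * (mult if row.tissue == "tumor" else 1.0)
        cols[row.sample_id] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    vf = pd.DataFrame(
        columns=["sample_id", "transcript_id", "position", "ref", "alt", "fraction"]
    )
    return GroundTruth(molecule_counts=counts, variant_fractions=vf, samples=sheet)


# ---------------------------------------------------------------------------
# Read rendering
# ---------------------------------------------------------------------------


def _apply_variant(window: str, probe: SmMIPProbe, v: SpikedVariant) -> str:
    off = v.position - probe.target_start
    return window[:off] + v.alt + window[off + len(v.ref) :]


def _draw_umis(n: int, umi_length: int, rng: np.random.Generator) -> list[str]:
    """n distinct UMIs of the given length.

    Distinctness within one (sample, probe) cell keeps the true molecule
    count identifiable from the reads; at the default 4^8 UMI space the
    difference from fully independent draws is negligible.
    """
    space = 4**umi_length
    if n > space:
        raise SimulationError(f"cannot draw {n} distinct UMIs of length {umi_length}")
    codes = rng.integers(0, space, size=n)
    seen = set()
    for i in range(n):
        while int(codes[i]) in seen:
            codes[i] = rng.integers(0, space)
        seen.add(int(codes[i]))
    out = []
    for c in codes:
        c = int(c)
        umi = []
        for _ in range(umi_length):
            umi.append("ACGT"[c & 3])
            c >>= 2
        out.append("".join(umi))
    return out


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


@dataclass
class CohortSimulation:
    """Simulated reads plus ground truth for one cohort."""

    reads: dict[str, list[tuple[str, str]]]  # sample_id -> [(read_id, sequence)]
    truth: GroundTruth
    config: SimulationConfig

    def write_fastq(self, out_dir) -> dict[str, Path]:
        """One uncompressed 4-line FASTQ per sample; constant quality 'I'."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample_id, records in self.reads.items():
            path = out_dir / f"{sample_id}.fastq"
            with open(path, "w") as fh:
                for read_id, seq in records:
                    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[sample_id] = path
        return paths


def simulate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Render a full cohort of smMIP reads with PCR duplicates and errors.

    Per molecule: a random UMI of the probe's UMI length, a gap fill equal
    to the reference window (or the spiked alternate allele), the probe's
    arms, then ``Geometric(1/duplication_mean)`` identical copies (support
    >= 1, mean = duplication_mean) each independently subjected to uniform
    base errors.  Fully reproducible from ``config.seed``.
    """
    truth = simulate_molecule_counts(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    panel = config.panel
    variants_by_probe: dict[str, list[SpikedVariant]] = {}
    for v in config.spiked_variants:
        for probe in panel.probes_for_transcript(v.transcript_id):
            if (
                probe.target_start <= v.position
                and v.position + len(v.ref) <= probe.target_end
            ):
                variants_by_probe.setdefault(probe.probe_id, []).append(v)

    reads: dict[str, list[tuple[str, str]]] = {}
    vf_rows = []
    counter = itertools.count()
    for _, srow in truth.samples.iterrows():
        sample_id = srow.sample_id
        is_tumor = srow.tissue == "tumor"
        records: list[tuple[str, str]] = []
        variant_molecules: dict[tuple, int] = {}
        covering_molecules: dict[tuple, int] = {}
        for probe in panel.probes:
            n_mol = int(truth.molecule_counts.at[probe.probe_id, sample_id])
            if n_mol == 0:
                continue
            window = panel.target_window(probe)
            active = [
                v
                for v in variants_by_probe.get(probe.probe_id, [])
                if is_tumor or not v.tumor_only
            ]
            observable = variants_by_probe.get(probe.probe_id, [])
            for v in observable:
                covering_molecules[v.key] = covering_molecules.get(v.key, 0) + n_mol
            umis = _draw_umis(n_mol, probe.umi_length, rng)
            for umi in umis:
                fill = window
                for v in active:
                    if rng.random() < v.vaf:
                        fill = _apply_variant(window, probe, v)
                        variant_molecules[v.key] = variant_molecules.get(v.key, 0) + 1
                        break  # at most one variant per molecule
                template = umi + probe.extension_arm + fill + probe.ligation_arm
                n_copies = (
                    1
                    if config.duplication_mean == 1
                    else int(rng.geometric(1.0 / config.duplication_mean))
                )
                for _ in range(n_copies):
                    seq = _mutate(template, rng, config.error_rate)
                    records.append((f"{sample_id}:{probe.probe_id}:{next(counter)}", seq))
        reads[sample_id] = records
        for v in config.spiked_variants:
            cov = covering_molecules.get(v.key, 0)
            vf_rows.append(
                {
                    "sample_id": sample_id,
                    "transcript_id": v.transcript_id,
                    "position": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "fraction": variant_molecules.get(v.key, 0) / cov if cov else 0.0,
                }
            )
    truth.variant_fractions = pd.DataFrame(
        vf_rows,
        columns=["sample_id", "transcript_id", "position", "ref", "alt", "fraction"],
    )
    return CohortSimulation(reads=reads, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Expression design helpers
# ---------------------------------------------------------------------------


def design_effect_map(
    transcript_ids: list[str], n_up: int = 20, n_down: int = 20, fold: float = 4.0
) -> dict[str, float]:
    """Signed effect map over the first ``n_up + n_down`` transcripts.

    Mirrors the motivating design: a block of up-shifted transcripts
    (glycolysis-like) and a block of down-shifted ones (TCA-cycle-like),
    the rest null.
    """
    if fold < 1:
        raise SimulationError("fold must be >= 1")
    if n_up + n_down > len(transcript_ids):
        raise SimulationError("not enough transcripts for the requested design")
    out: dict[str, float] = {}
    for tid in transcript_ids[:n_up]:
        out[tid] = fold
    for tid in transcript_ids[n_up : n_up + n_down]:
        out[tid] = -fold
    return out


# ---------------------------------------------------------------------------
# Dose-response simulation (median-effect model)
# ---------------------------------------------------------------------------


def simulate_dose_response(
    dm: float,
    m: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_id: str = "drug",
) -> pd.DataFrame:
    """Fraction-affected values from the median-effect law with noise.

    fa(D) = (D/Dm)^m / (1 + (D/Dm)^m), multiplied by lognormal noise of
    sigma ``noise_sd`` and clipped into the open unit interval.  With
    ``noise_sd=0`` the model values are exact.
    """
    if dm <= 0 or m <= 0:
        raise SimulationError("dm and m must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise SimulationError("doses must be positive")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    ratio = (doses / dm) ** m
    fa = ratio / (1.0 + ratio)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa * rng.lognormal(mean=0.0, sigma=noise_sd, size=fa.size)
    eps = 1e-9
    fa = np.clip(fa, eps, 1.0 - eps)
    return pd.DataFrame({"drug": drug_id, "dose": doses, "fa": fa})
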