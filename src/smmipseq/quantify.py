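"""Read assignment, UMI consensus deduplication, and FPM expression.

Reads are assigned to probes by anchoring on the two targeting arms: after
stripping the leading UMI, the bases following it must match a probe's
extension arm and the read tail its ligation arm, each within a Hamming
mismatch budget.  All PCR copies sharing one (probe, UMI) pair collapse to
a single consensus "unique read"; unique-read counts are normalized per
sample to Fragments Per Million (FPM), and transcript expression is the
mean FPM over all probes targeting the transcript (zero-count probes
included).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .panel import PanelDefinition, SmMIPProbe

FPM_SCALE = 1_000_000

UNASSIGNED_REASONS = ("too_short", "no_match", "ambiguous")


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class AssignedRead:
    probe_id: str
    umi: str
    fill_sequence: str
    sample_id: str = ""


@dataclass(frozen=True)
class Unassigned:
    reason: str  # one of UNASSIGNED_REASONS


@dataclass(frozen=True)
class UniqueReadGroup:
    """Consensus of all PCR copies sharing one (probe, UMI) pair."""

    probe_id: str
    umi: str
    consensus_fill: str
    raw_read_count: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class ReadAssigner:
    """Arm-anchored read-to-probe assignment with an exact-match fast path."""

    def __init__(self, panel: PanelDefinition, max_arm_mismatches: int = 1):
        if max_arm_mismatches < 0:
            raise QuantificationError("max_arm_mismatches must be >= 0")
        self.panel = panel
        self.max_arm_mismatches = max_arm_mismatches
        # exact extension-arm index: (umi_length, arm_length) -> arm -> probes
        self._exact: dict[tuple[int, int], dict[str, list[SmMIPProbe]]] = {}
        for p in panel.probes:
            geo = (p.umi_length, len(p.extension_arm))
            self._exact.setdefault(geo, {}).setdefault(p.extension_arm, []).append(p)
        self._min_len = min(
            p.umi_length + len(p.extension_arm) + len(p.ligation_arm) + 1
            for p in panel.probes
        )

    def _arm_distances(self, seq: str, probe: SmMIPProbe) -> tuple[int, int] | None:
        start = probe.umi_length
        ext_end = start + len(probe.extension_arm)
        lig_start = len(seq) - len(probe.ligation_arm)
        if lig_start <= ext_end:
            return None  # no room for a fill
        ext_mm = _hamming(seq[start:ext_end], probe.extension_arm)
        if ext_mm > self.max_arm_mismatches:
            return None
        lig_mm = _hamming(seq[lig_start:], probe.ligation_arm)
        if lig_mm > self.max_arm_mismatches:
            return None
        return ext_mm, lig_mm

    def assign(self, seq: str, sample_id: str = "") -> AssignedRead | Unassigned:
        if len(seq) < self._min_len:
            return Unassigned("too_short")

        # fast path: exact extension arm and exact ligation arm
        exact_hit = None
        for (umi_len, arm_len), by_arm in self._exact.items():
            probes = by_arm.get(seq[umi_len : umi_len + arm_len])
            if not probes:
                continue
            for p in probes:
                lig_start = len(seq) - len(p.ligation_arm)
                if (
                    lig_start > umi_len + arm_len
                    and seq[lig_start:] == p.ligation_arm
                ):
                    if exact_hit is not None and exact_hit.probe_id != p.probe_id:
                        return Unassigned("ambiguous")
                    exact_hit = p
        if exact_hit is not None:
            # score 0 on both arms; any other probe scores >= 1
            return self._make(seq, exact_hit, sample_id)

        best_probes: list[SmMIPProbe] = []
        best_score = None
        for p in self.panel.probes:
            d = self._arm_distances(seq, p)
            if d is None:
                continue
            score = d[0] + d[1]
            if best_score is None or score < best_score:
                best_score, best_probes = score, [p]
            elif score == best_score:
                best_probes.append(p)
        if not best_probes:
            return Unassigned("no_match")
        if len(best_probes) > 1:
            return Unassigned("ambiguous")
        return self._make(seq, best_probes[0], sample_id)

    @staticmethod
    def _make(seq: str, probe: SmMIPProbe, sample_id: str) -> AssignedRead:
        start = probe.umi_length
        fill = seq[start + len(probe.extension_arm) : len(seq) - len(probe.ligation_arm)]
        return AssignedRead(
            probe_id=probe.probe_id,
            umi=seq[:start],
            fill_sequence=fill,
            sample_id=sample_id,
        )


def assign_read(
    seq: str,
    panel: PanelDefinition,
    max_arm_mismatches: int = 1,
    sample_id: str = "",
) -> AssignedRead | Unassigned:
    """Assign one read sequence to its probe (convenience wrapper)."""
    return ReadAssigner(panel, max_arm_mismatches).assign(seq, sample_id)


def assign_fastq(
    fastq_path,
    panel: PanelDefinition,
    sample_id: str,
    max_arm_mismatches: int = 1,
) -> tuple[list[AssignedRead], dict[str, int]]:
    """Assign every read of one sample FASTQ; returns reads + reason tallies."""
    assigner = ReadAssigner(panel, max_arm_mismatches)
    reads: list[AssignedRead] = []
    stats = {"assigned": 0, **{r: 0 for r in UNASSIGNED_REASONS}}
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        out = assigner.assign(str(rec.seq), sample_id)
        if isinstance(out, AssignedRead):
            reads.append(out)
            stats["assigned"] += 1
        else:
            stats[out.reason] += 1
    return reads, stats


def _consensus(fills: list[str], reference_window: str | None) -> str:
    """Per-position majority vote; ties fall back to the reference base
    when it is among the tied candidates, else 'N'.

    If fill lengths differ within the group (indel-bearing errors), the
    vote runs over the majority length, earliest-seen on ties.
    """
    lengths = Counter(len(f) for f in fills)
    top = max(lengths.values())
    length = next(n for f in fills if (n := len(f)) and lengths[n] == top)
    voters = [f for f in fills if len(f) == length]
    positional_ref = (
        reference_window
        if reference_window is not None and len(reference_window) == length
        else None
    )
    out = []
    for i in range(length):
        counts = Counter(f[i] for f in voters)
        best = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == best)
        if len(tied) == 1:
            out.append(tied[0])
        elif positional_ref is not None and positional_ref[i] in tied:
            out.append(positional_ref[i])
        else:
            out.append("N")
    return "".join(out)


def dedupe(
    reads: list[AssignedRead], panel: PanelDefinition | None = None
) -> list[UniqueReadGroup]:
    """Collapse PCR duplicates: one consensus read per (probe, UMI) pair.

    All reads must come from a single sample.  Passing the panel enables
    reference-aware tie-breaking in the consensus vote.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for r in reads:
        groups[(r.probe_id, r.umi)].append(r.fill_sequence)
    out = []
    for (probe_id, umi), fills in groups.items():
        ref_window = None
        if panel is not None:
            ref_window = panel.target_window(panel.probe(probe_id))
        out.append(
            UniqueReadGroup(
                probe_id=probe_id,
                umi=umi,
                consensus_fill=_consensus(fills, ref_window),
                raw_read_count=len(fills),
            )
        )
    out.sort(key=lambda g: (g.probe_id, g.umi))
    return out


def count_unique(
    groups_by_sample: dict[str, list[UniqueReadGroup]], panel: PanelDefinition
) -> pd.DataFrame:
    """Probe x sample matrix of unique-read counts (zeros included)."""
    probe_ids = [p.probe_id for p in panel.probes]
    mat = pd.DataFrame(
        0,
        index=pd.Index(probe_ids, name="probe_id"),
        columns=list(groups_by_sample),
        dtype=int,
    )
    for sample_id, groups in groups_by_sample.items():
        tally = Counter(g.probe_id for g in groups)
        for probe_id, n in tally.items():
            mat.at[probe_id, sample_id] = n
    return mat


def to_fpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Fragments Per Million: per-sample normalization to a 10^6 total."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise QuantificationError(
            f"sample(s) with zero total unique reads: {list(zero.index)}"
        )
    return counts / totals * FPM_SCALE


def transcript_expression(fpm: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    """Transcript x sample mean FPM over ALL probes of each transcript.

    Zero-count probes are included in the mean, matching the panel-wide
    normalization convention.
    """
    probe_to_tx = {p.probe_id: p.transcript_id for p in panel.probes}
    missing = [pid for pid in fpm.index if pid not in probe_to_tx]
    if missing:
        raise QuantificationError(f"probes not in panel: {missing[:5]}")
    tx = fpm.groupby([probe_to_tx[pid] for pid in fpm.index]).mean()
    tx.index.name = "transcript_id"
    for tid in panel.transcript_ids:
        if tid not in tx.index:
            raise QuantificationError(f"transcript {tid!r} has no probes in matrix")
    return tx


def quantify_cohort(
    sequences_by_sample: dict[str, list[str]],
    panel: PanelDefinition,
    max_arm_mismatches: int = 1,
) -> tuple[dict[str, list[UniqueReadGroup]], pd.DataFrame, dict[str, dict[str, int]]]:
    """Assign, dedupe and count every sample; returns (groups, counts, stats).

    ``sequences_by_sample`` maps sample_id to raw read sequences (strings).
    """
    assigner = ReadAssigner(panel, max_arm_mismatches)
    groups_by_sample: dict[str, list[UniqueReadGroup]] = {}
    stats: dict[str, dict[str, int]] = {}
    for sample_id, seqs in sequences_by_sample.items():
        assigned: list[AssignedRead] = []
        tally = {"assigned": 0, **{r: 0 for r in UNASSIGNED_REASONS}}
        for seq in seqs:
            out = assigner.assign(seq, sample_id)
            if isinstance(out, AssignedRead):
                assigned.append(out)
                tally["assigned"] += 1
            else:
                tally[out.reason] += 1
        groups_by_sample[sample_id] = dedupe(assigned, panel)
        stats[sample_id] = tally
    counts = count_unique(groups_by_sample, panel)
    return groups_by_sample, counts, stats


def quantify_sample_reads(
    reads_by_sample: dict[str, list[AssignedRead]], panel: PanelDefinition
) -> dict[str, list[UniqueReadGroup]]:
    """Dedupe each sample's assigned reads (reference-aware consensus)."""
    return {s: dedupe(reads, panel) for s, reads in reads_by_sample.items()}
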