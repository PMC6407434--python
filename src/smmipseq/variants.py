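"""Variant calling from UMI-consensus reads and somatic classification.

Calls are made per sample from a pileup of unique (UMI-collapsed) reads:
every non-reference allele whose variant-allele fraction (VAF = variant
unique reads / total unique-read coverage) reaches the reporting threshold
(default 10%) at sufficient unique-read coverage is emitted.  A tumor call
is classified somatic when the same allele is essentially absent from the
patient's matched healthy sample; insufficient healthy coverage yields an
explicit ``not_evaluable`` state rather than a silent negative.

Coordinates are 0-based transcript positions internally; the VCF writer
converts to 1-based POS.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import edlib

from .panel import PanelDefinition
from .quantify import UniqueReadGroup

DEFAULT_MIN_VAF = 0.10
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MAX_NORMAL_VAF = 0.02
DEFAULT_MAX_GAP = 10

# allele keys: a single base for substitutions/reference,
# or an ("indel", ref, alt) tuple anchored at its position
AlleleKey = str | tuple[str, str, str]


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    transcript_id: str
    position: int  # 0-based transcript coordinate (anchor base for indels)
    ref: str
    alt: str
    variant_unique_reads: int
    total_unique_reads: int
    somatic: bool | None = None  # None = not_evaluable against the matched normal

    @property
    def vaf(self) -> float:
        return self.variant_unique_reads / self.total_unique_reads

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.position, self.ref, self.alt)


@dataclass
class Pileup:
    """Per-position allele counts over unique consensus reads.

    ``alleles[(transcript_id, pos)]`` maps allele keys to unique-read
    counts; ``coverage[(transcript_id, pos)]`` is the number of unique
    reads spanning the position ('N' consensus bases count toward
    coverage but not toward any allele).
    """

    alleles: dict[tuple[str, int], dict[AlleleKey, int]]
    coverage: dict[tuple[str, int], int]
    skipped_groups: int = 0

    def allele_fraction(self, transcript_id: str, position: int, allele: AlleleKey) -> float:
        cov = self.coverage.get((transcript_id, position), 0)
        if cov == 0:
            return 0.0
        return self.alleles.get((transcript_id, position), {}).get(allele, 0) / cov


def left_align_indel(ref_seq: str, position: int, ref: str, alt: str):
    """Shift an anchored indel left through repeats to its canonical form.

    ``ref``/``alt`` share their first (anchor) base at ``position``.  A
    deletion of interval [d, d+L) can start one base earlier whenever
    ref_seq[d-1] == ref_seq[d+L-1]; an insertion of S after the anchor can
    move left whenever its last base equals the anchor base (rotating S).
    """
    if len(ref) > len(alt) and len(alt) == 1:  # deletion
        d = position + 1
        L = len(ref) - 1
        while d > 1 and ref_seq[d - 1] == ref_seq[d + L - 1]:
            d -= 1
        position = d - 1
        ref = ref_seq[position : position + L + 1]
        alt = ref_seq[position]
    elif len(alt) > len(ref) and len(ref) == 1:  # insertion
        a = position
        inserted = alt[1:]
        while a > 0 and inserted[-1] == ref_seq[a]:
            inserted = ref_seq[a] + inserted[:-1]
            a -= 1
        position = a
        ref = ref_seq[a]
        alt = ref + inserted
    return position, ref, alt


def _events_from_alignment(
    fill: str, window: str, start: int, window_seq_offset: int = 0
):
    """Yield (position, allele_key) events by aligning fill vs reference.

    Substitution events carry the observed base; indels are anchored on
    the preceding reference base, VCF-style.
    """
    res = edlib.align(fill, window, task="path", mode="NW")
    cigar = res["cigar"]
    events = []
    qi = 0  # fill index
    ri = 0  # window index
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            for k in range(n):
                events.append((start + ri + k, fill[qi + k]))
            qi += n
            ri += n
        elif ch == "X":
            for k in range(n):
                events.append((start + ri + k, fill[qi + k]))
            qi += n
            ri += n
        elif ch == "I":  # bases present in fill, absent from reference
            anchor = ri - 1
            if anchor >= 0:
                ref_b = window[anchor]
                events.append(
                    (start + anchor, ("indel", ref_b, ref_b + fill[qi : qi + n]))
                )
            qi += n
        elif ch == "D":  # bases present in reference, absent from fill
            anchor = ri - 1
            if anchor >= 0:
                ref_b = window[anchor]
                events.append(
                    (start + anchor, ("indel", ref_b + window[ri : ri + n], ref_b))
                )
            ri += n
    return events


def build_pileup(
    groups: list[UniqueReadGroup],
    panel: PanelDefinition,
    max_gap: int = DEFAULT_MAX_GAP,
) -> Pileup:
    """Pile up consensus fills against each probe's reference window.

    Fills of reference length are compared positionally; length-changed
    fills are aligned with a bounded-gap global alignment to locate
    indels.  Fills whose length differs from the window by more than
    ``max_gap`` are skipped and tallied.
    """
    alleles: dict[tuple[str, int], dict[AlleleKey, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    coverage: dict[tuple[str, int], int] = defaultdict(int)
    skipped = 0
    probe_map = {p.probe_id: p for p in panel.probes}
    for g in groups:
        probe = probe_map[g.probe_id]
        window = panel.target_window(probe)
        tid = probe.transcript_id
        start = probe.target_start
        fill = g.consensus_fill
        if abs(len(fill) - len(window)) > max_gap:
            skipped += 1
            continue
        for pos in range(start, probe.target_end):
            coverage[(tid, pos)] += 1
        if len(fill) == len(window):
            for k, base in enumerate(fill):
                if base != "N":
                    alleles[(tid, start + k)][base] += 1
        else:
            ref_seq = panel.transcripts[tid]
            for pos, key in _events_from_alignment(fill, window, start):
                if isinstance(key, tuple):
                    _, ref, alt = key
                    lpos, lref, lalt = left_align_indel(ref_seq, pos, ref, alt)
                    if lpos >= start:
                        alleles[(tid, lpos)][("indel", lref, lalt)] += 1
                elif key != "N":
                    alleles[(tid, pos)][key] += 1
    return Pileup(
        alleles={k: dict(v) for k, v in alleles.items()},
        coverage=dict(coverage),
        skipped_groups=skipped,
    )


def call_variants(
    pileup: Pileup,
    panel: PanelDefinition,
    sample_id: str = "",
    min_vaf: float = DEFAULT_MIN_VAF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[VariantCall]:
    """Emit every non-reference allele with VAF >= min_vaf at sufficient
    unique-read coverage, sorted by (transcript, position)."""
    if not 0 < min_vaf <= 1:
        raise VariantError(f"min_vaf must be in (0, 1], got {min_vaf}")
    calls = []
    for (tid, pos), allele_counts in pileup.alleles.items():
        cov = pileup.coverage.get((tid, pos), 0)
        if cov < min_coverage or cov == 0:
            continue
        ref_base = panel.transcripts[tid][pos]
        for key, n in allele_counts.items():
            if key == ref_base:
                continue
            if n / cov < min_vaf:
                continue
            if isinstance(key, tuple):
                _, ref, alt = key
            else:
                ref, alt = ref_base, key
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    transcript_id=tid,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    variant_unique_reads=n,
                    total_unique_reads=cov,
                )
            )
    calls.sort(key=lambda c: (c.transcript_id, c.position, c.alt))
    return calls


def classify_somatic(
    tumor_calls: list[VariantCall],
    healthy_pileup: Pileup,
    max_normal_vaf: float = DEFAULT_MAX_NORMAL_VAF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[VariantCall]:
    """Mark each tumor call somatic / germline-or-artifact / not_evaluable.

    somatic=True: allele fraction in the matched healthy pileup is at most
    ``max_normal_vaf`` at coverage >= min_coverage.  somatic=None: healthy
    coverage below the floor, so absence cannot be asserted.
    """
    out = []
    for call in tumor_calls:
        cov = healthy_pileup.coverage.get((call.transcript_id, call.position), 0)
        if cov < min_coverage:
            out.append(replace(call, somatic=None))
            continue
        if isinstance(call.ref, str) and len(call.ref) == 1 and len(call.alt) == 1:
            key: AlleleKey = call.alt
        else:
            key = ("indel", call.ref, call.alt)
        frac = healthy_pileup.allele_fraction(call.transcript_id, call.position, key)
        out.append(replace(call, somatic=frac <= max_normal_vaf))
    return out


def write_vcf(calls: list[VariantCall], path, panel: PanelDefinition) -> None:
    """Minimal VCF 4.2 with transcript IDs as contigs (POS is 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VUR,Number=1,Type=Integer,Description="Variant unique reads">\n')
        fh.write('##INFO=<ID=TUR,Number=1,Type=Integer,Description="Total unique reads">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">\n')
        fh.write('##INFO=<ID=SOMATIC,Number=1,Type=String,Description="somatic status vs matched normal">\n')
        for tid in sorted({c.transcript_id for c in calls}):
            fh.write(f"##contig=<ID={tid},length={len(panel.transcripts[tid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            somatic = {True: "yes", False: "no", None: "not_evaluable"}[c.somatic]
            info = (
                f"VUR={c.variant_unique_reads};TUR={c.total_unique_reads};"
                f"VAF={c.vaf:.4f};SOMATIC={somatic}"
            )
            fh.write(
                f"{c.transcript_id}\t{c.position + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )
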