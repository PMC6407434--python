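"""smMIP panel model: probes, reference transcripts, and panel IO.

A single-molecule molecular inversion probe (smMIP) captures a fixed window
of a transcript between two targeting arms (extension and ligation arm) and
carries a random unique molecule identifier (UMI) that tags the original
cDNA molecule.  A panel is the set of probes used in one capture reaction
together with the reference sequences of the transcripts they target.

Coordinates are 0-based, half-open, in transcript space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

_VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = [
    "probe_id",
    "transcript_id",
    "extension_arm",
    "ligation_arm",
    "umi_length",
    "target_start",
    "target_end",
    "strand",
]


class PanelError(ValueError):
    """Raised when a panel definition is internally inconsistent."""


@dataclass(frozen=True)
class SmMIPProbe:
    """One smMIP: targeting arms, UMI geometry and target window.

    The target window ``[target_start, target_end)`` is the gap-fill region
    read out between the two arms, in 0-based half-open transcript
    coordinates.  Arms are stored in read orientation.
    """

    probe_id: str
    transcript_id: str
    extension_arm: str
    ligation_arm: str
    umi_length: int = 8
    target_start: int = 0
    target_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        for name in ("extension_arm", "ligation_arm"):
            arm = getattr(self, name)
            if not arm or not set(arm) <= _VALID_BASES:
                raise PanelError(
                    f"probe {self.probe_id!r}: {name} must be a non-empty "
                    f"string over A/C/G/T, got {arm!r}"
                )
        if self.umi_length < 1:
            raise PanelError(f"probe {self.probe_id!r}: umi_length must be >= 1")
        if not self.target_start < self.target_end:
            raise PanelError(
                f"probe {self.probe_id!r}: target_start must be < target_end "
                f"({self.target_start} >= {self.target_end})"
            )
        if self.target_start < 0:
            raise PanelError(f"probe {self.probe_id!r}: negative target_start")
        if self.strand not in ("+", "-"):
            raise PanelError(f"probe {self.probe_id!r}: strand must be '+' or '-'")

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class PanelDefinition:
    """A validated set of probes plus the reference transcripts they target."""

    probes: list[SmMIPProbe]
    transcripts: dict[str, str]
    _by_transcript: dict[str, list[SmMIPProbe]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for probe in self.probes:
            if probe.probe_id in seen:
                raise PanelError(f"duplicate probe_id {probe.probe_id!r}")
            seen.add(probe.probe_id)
            ref = self.transcripts.get(probe.transcript_id)
            if ref is None:
                raise PanelError(
                    f"probe {probe.probe_id!r} references unknown transcript "
                    f"{probe.transcript_id!r}"
                )
            if probe.target_end > len(ref):
                raise PanelError(
                    f"probe {probe.probe_id!r}: target_end {probe.target_end} "
                    f"beyond length {len(ref)} of transcript "
                    f"{probe.transcript_id!r}"
                )
            self._by_transcript.setdefault(probe.transcript_id, []).append(probe)
        for probes in self._by_transcript.values():
            probes.sort(key=lambda p: p.probe_id)

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self._by_transcript)

    def probes_for_transcript(self, transcript_id: str) -> list[SmMIPProbe]:
        """All probes targeting ``transcript_id``, in probe_id order."""
        if transcript_id not in self.transcripts:
            raise KeyError(f"unknown transcript {transcript_id!r}")
        return list(self._by_transcript.get(transcript_id, []))

    def probe(self, probe_id: str) -> SmMIPProbe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(f"unknown probe {probe_id!r}")

    def target_window(self, probe: SmMIPProbe) -> str:
        """Reference sequence of the probe's gap-fill window."""
        return self.transcripts[probe.transcript_id][
            probe.target_start : probe.target_end
        ]


def probes_for_transcript(
    panel: PanelDefinition, transcript_id: str
) -> list[SmMIPProbe]:
    return panel.probes_for_transcript(transcript_id)


def load_panel(panel_table_path, reference_fasta_path) -> PanelDefinition:
    """Read a panel from a tab-separated probe table and a reference FASTA.

    The table must carry the header columns
    ``probe_id / transcript_id / extension_arm / ligation_arm / umi_length /
    target_start / target_end / strand``.  Every referenced transcript must
    be present in the FASTA; coordinates are validated against sequence
    lengths.
    """
    try:
        table = pd.read_csv(panel_table_path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"cannot read panel table {panel_table_path}: {exc}")
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise PanelError(f"panel table missing columns {missing}")

    transcripts = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(reference_fasta_path), "fasta")
    }

    probes = []
    for idx, row in table.iterrows():
        try:
            probes.append(
                SmMIPProbe(
                    probe_id=row["probe_id"],
                    transcript_id=row["transcript_id"],
                    extension_arm=str(row["extension_arm"]).upper(),
                    ligation_arm=str(row["ligation_arm"]).upper(),
                    umi_length=int(row["umi_length"]),
                    target_start=int(row["target_start"]),
                    target_end=int(row["target_end"]),
                    strand=row["strand"],
                )
            )
        except PanelError:
            raise
        except (TypeError, ValueError) as exc:
            raise PanelError(f"malformed panel row {idx + 1}: {exc}")
    return PanelDefinition(probes=probes, transcripts=transcripts)


def write_panel(panel: PanelDefinition, panel_table_path, reference_fasta_path) -> None:
    """Write the panel in the same dialect :func:`load_panel` reads."""
    rows = [
        {
            "probe_id": p.probe_id,
            "transcript_id": p.transcript_id,
            "extension_arm": p.extension_arm,
            "ligation_arm": p.ligation_arm,
            "umi_length": p.umi_length,
            "target_start": p.target_start,
            "target_end": p.target_end,
            "strand": p.strand,
        }
        for p in panel.probes
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(
        panel_table_path, sep="\t", index=False
    )
    with open(reference_fasta_path, "w") as fh:
        for tid in sorted(panel.transcripts):
            fh.write(f">{tid}\n{panel.transcripts[tid]}\n")
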