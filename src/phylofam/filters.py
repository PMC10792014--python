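"""Candidate-sequence curation rules.

Three independent decision rules, all consuming *externally produced*
predictions (transmembrane-domain counts, signal-peptide calls) merged with
the sequences themselves:

* N-terminal cysteine-motif classification (CC / CXC / CX3C / XC / none),
  using the standard nomenclature spacing of the first two cysteines;
* transmembrane-domain count range filter (default keep 5-8);
* advisory flags: within-group sequence-length outliers and missing signal
  peptides. Flags never silently drop records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CandidateRecord",
    "MotifCall",
    "TMVerdict",
    "scan_cysteine_motif",
    "count_cysteines",
    "tm_filter",
    "flag_candidates",
    "read_candidates",
    "candidate_report",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX*-")


@dataclass
class CandidateRecord:
    id: str
    sequence: str
    species: str | None = None
    tm_count: int | None = None
    signal_peptide: bool | None = None
    group: str | None = None
    top_hit: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifCall:
    category: str  # CC | CXC | CX3C | XC | none
    cysteine_positions: tuple[int, ...]  # 0-based, within the full sequence
    window: tuple[int, int]  # [start, end) actually scanned


def scan_cysteine_motif(
    sequence: str, window: int = 60, offset: int = 0
) -> MotifCall:
    """Classify the N-terminal cysteine spacing.

    Within ``sequence[offset:offset+window]`` the first two cysteines decide
    the class: adjacent -> CC, one residue between -> CXC, three between ->
    CX3C; exactly one cysteine in the window -> XC; anything else (no
    cysteine, or spacing of 2 or >= 4) -> none. 'X' is an unknown residue
    and never counts as cysteine.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    start, end = offset, min(offset + window, len(seq))
    positions = [i for i in range(start, end) if seq[i] == "C"]
    if not positions:
        return MotifCall("none", (), (start, end))
    if len(positions) == 1:
        return MotifCall("XC", (positions[0],), (start, end))
    first, second = positions[0], positions[1]
    gap = second - first - 1
    category = {0: "CC", 1: "CXC", 3: "CX3C"}.get(gap, "none")
    return MotifCall(category, (first, second), (start, end))


def count_cysteines(sequence: str, start: int = 0, end: int | None = None) -> int:
    """Exact cysteine count in ``sequence[start:end]``."""
    return sequence.upper()[start:end].count("C")


@dataclass(frozen=True)
class TMVerdict:
    keep: bool
    reason: str


def tm_filter(
    record: CandidateRecord | int | None, min_tm: int = 5, max_tm: int = 8
) -> TMVerdict:
    """Keep iff the predicted transmembrane-domain count is within
    ``[min_tm, max_tm]``; records without a prediction are rejected with
    reason ``no-prediction``."""
    count = record.tm_count if isinstance(record, CandidateRecord) else record
    if count is None:
        return TMVerdict(False, "no-prediction")
    if min_tm <= count <= max_tm:
        return TMVerdict(True, "in-range")
    return TMVerdict(False, "below-range" if count < min_tm else "above-range")


def flag_candidates(
    records: list[CandidateRecord],
    length_zscore_cut: float = 2.5,
    require_signal_peptide: bool = False,
) -> pd.DataFrame:
    """Advisory per-record report: length-outlier z-flags (computed within
    each record's group) and signal-peptide checks.

    Groups with fewer than 3 members get no length flags (a warning is
    emitted). Verdict is ``suspect`` if any flag fires, else ``keep``;
    nothing is dropped.
    """
    rows = []
    by_group: dict[str | None, list[CandidateRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)

    zscores: dict[str, float] = {}
    for group, members in by_group.items():
        if len(members) < 3:
            warnings.warn(
                f"group {group!r} has fewer than 3 records; "
                "length flags skipped",
                stacklevel=2,
            )
            continue
        lengths = np.array([m.length for m in members], dtype=float)
        sd = lengths.std(ddof=1)
        for m in members:
            zscores[m.id] = (
                0.0 if sd == 0 else float((m.length - lengths.mean()) / sd)
            )

    for rec in records:
        z = zscores.get(rec.id, np.nan)
        length_outlier = bool(abs(z) > length_zscore_cut) if not np.isnan(z) else False
        missing_sp = bool(require_signal_peptide and not rec.signal_peptide)
        reasons = []
        if length_outlier:
            reasons.append("length-outlier")
        if missing_sp:
            reasons.append("no-signal-peptide")
        rows.append(
            {
                "id": rec.id,
                "group": rec.group,
                "length": rec.length,
                "length_z": z,
                "length_outlier": length_outlier,
                "signal_peptide": rec.signal_peptide,
                "verdict": "suspect" if reasons else "keep",
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("id")


def read_candidates(
    fasta_path: str, annotations_path: str | None = None
) -> list[CandidateRecord]:
    """Load sequences (FASTA) and merge the external prediction table
    (TSV with columns ``id``, and optionally ``tm_count``,
    ``signal_peptide``, ``species``, ``group``, ``top_hit``)."""
    records = [
        CandidateRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(fasta_path, "fasta")
    ]
    if annotations_path is not None:
        table = pd.read_csv(annotations_path, sep="\t").set_index("id")
        for rec in records:
            if rec.id not in table.index:
                continue
            row = table.loc[rec.id]
            if "tm_count" in row and pd.notna(row.get("tm_count")):
                rec.tm_count = int(row["tm_count"])
            if "signal_peptide" in row and pd.notna(row.get("signal_peptide")):
                rec.signal_peptide = bool(row["signal_peptide"])
            for attr in ("species", "group", "top_hit"):
                if attr in row and pd.notna(row.get(attr)):
                    setattr(rec, attr, str(row[attr]))
    return records


def candidate_report(
    records: list[CandidateRecord],
    window: int = 60,
    offset: int = 0,
    min_tm: int = 5,
    max_tm: int = 8,
    length_zscore_cut: float = 2.5,
    require_signal_peptide: bool = False,
) -> pd.DataFrame:
    """Full curation table: motif class, cysteine counts, TM verdict and
    advisory flags, one row per record."""
    flags = flag_candidates(
        records,
        length_zscore_cut=length_zscore_cut,
        require_signal_peptide=require_signal_peptide,
    )
    rows = []
    for rec in records:
        motif = scan_cysteine_motif(rec.sequence, window=window, offset=offset)
        verdict = tm_filter(rec, min_tm=min_tm, max_tm=max_tm)
        rows.append(
            {
                "id": rec.id,
                "motif_class": motif.category,
                "cysteines_window": count_cysteines(
                    rec.sequence, motif.window[0], motif.window[1]
                ),
                "cysteines_total": count_cysteines(rec.sequence),
                "tm_count": rec.tm_count,
                "tm_keep": verdict.keep,
                "tm_reason": verdict.reason,
                "top_hit": rec.top_hit,
            }
        )
    report = pd.DataFrame(rows).set_index("id")
    return report.join(flags, how="left")
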