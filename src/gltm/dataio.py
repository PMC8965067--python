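"""Fragment records and file I/O (FASTA sequences, TSV annotations, TSV localization tables).

Coordinates are 0-based half-open everywhere, both in memory and on disk.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid letters, in the channel order used by the encoder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DIMER = "dimer"
NON_DIMER = "non-dimer"
UNKNOWN = "unknown"
LABELS = frozenset({DIMER, NON_DIMER, UNKNOWN})

ANNOTATION_COLUMNS = ("fragment_id", "label", "motif_start", "motif_end")
LOCALIZATION_COLUMNS = (
    "fragment_id",
    "predicted_label",
    "true_times",
    "residue_index",
    "votes",
    "tier",
)


def validate_sequence(sequence: str, record_name: str = "sequence") -> None:
    """Raise ``ValueError`` naming the offending position if *sequence* leaves the
    20-letter amino-acid alphabet."""
    for pos, letter in enumerate(sequence):
        if letter not in AA_INDEX:
            raise ValueError(
                f"{record_name}: non-standard residue {letter!r} at position {pos}"
            )


@dataclass
class Fragment:
    """A fixed-length amino-acid fragment with an optional label and motif interval.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header).
    sequence : str
        Amino-acid string over the 20 standard letters.
    label : str
        One of ``"dimer"``, ``"non-dimer"``, ``"unknown"``.
    motif_interval : tuple of (int, int), optional
        0-based half-open ``[start, end)`` interval of a known motif.
    """

    id: str
    sequence: str
    label: str = UNKNOWN
    motif_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        validate_sequence(self.sequence, f"fragment {self.id!r}")
        if self.label not in LABELS:
            raise ValueError(f"fragment {self.id!r}: unknown label {self.label!r}")
        if self.motif_interval is not None:
            start, end = self.motif_interval
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"fragment {self.id!r}: motif interval [{start}, {end}) out of "
                    f"bounds for length {len(self.sequence)}"
                )
            self.motif_interval = (int(start), int(end))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def motif_center(self) -> Optional[float]:
        """Midpoint of the motif interval (may be half-integral), or ``None``."""
        if self.motif_interval is None:
            return None
        start, end = self.motif_interval
        return (start + end) / 2.0


def read_fragments(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> list[Fragment]:
    """Read fragments from FASTA, joining labels/motif intervals from a TSV table by id.

    Fragments absent from the annotation table get ``label="unknown"``.

    Raises
    ------
    ValueError
        On a malformed FASTA record or a non-standard residue letter.
    KeyError
        If an annotation row references an id that is not in the FASTA file.
    """
    fasta_path = Path(fasta_path)
    fragments: dict[str, Fragment] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if not record.id:
            raise ValueError(f"{fasta_path}: FASTA record with empty id")
        if not seq:
            raise ValueError(f"{fasta_path}: FASTA record {record.id!r} has no sequence")
        fragments[record.id] = Fragment(id=record.id, sequence=seq)
    if not fragments:
        raise ValueError(f"{fasta_path}: no FASTA records found")

    if annotation_path is not None:
        for row in _read_tsv(annotation_path, ANNOTATION_COLUMNS):
            frag_id = row["fragment_id"]
            if frag_id not in fragments:
                raise KeyError(
                    f"{annotation_path}: annotation id {frag_id!r} not present in "
                    f"{fasta_path}"
                )
            interval = None
            if row["motif_start"] != "" and row["motif_end"] != "":
                interval = (int(row["motif_start"]), int(row["motif_end"]))
            old = fragments[frag_id]
            fragments[frag_id] = Fragment(
                id=frag_id,
                sequence=old.sequence,
                label=row["label"],
                motif_interval=interval,
            )
    return list(fragments.values())


def write_fragments(
    fragments: Iterable[Fragment],
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write fragment sequences as FASTA and, optionally, labels/intervals as TSV."""
    fragments = list(fragments)
    records = [
        SeqRecord(Seq(f.sequence), id=f.id, description="") for f in fragments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotation_path is not None:
        with open(annotation_path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(ANNOTATION_COLUMNS)
            for f in fragments:
                start, end = ("", "")
                if f.motif_interval is not None:
                    start, end = f.motif_interval
                writer.writerow([f.id, f.label, start, end])


def extract_fragment(
    full_sequence: str,
    tm_interval: tuple[int, int],
    out_length: int = 40,
    fragment_id: str = "fragment",
) -> Fragment:
    """Cut a window of exactly *out_length* residues centered on the midpoint of
    *tm_interval*, clamped to the sequence bounds.

    Raises ``ValueError`` if the sequence is shorter than *out_length*.
    """
    L = len(full_sequence)
    if L < out_length:
        raise ValueError(
            f"sequence length {L} is shorter than requested fragment length {out_length}"
        )
    start, end = tm_interval
    if not (0 <= start < end <= L):
        raise ValueError(f"TM interval [{start}, {end}) out of bounds for length {L}")
    mid = (start + end) / 2.0
    win_start = int(math.floor(mid - out_length / 2.0 + 0.5))
    win_start = max(0, min(win_start, L - out_length))
    return Fragment(
        id=fragment_id, sequence=full_sequence[win_start : win_start + out_length]
    )


def write_localization(results: Iterable, path: str | Path) -> None:
    """Serialize localization results to a TSV, one row per residue.

    Columns: ``fragment_id predicted_label true_times residue_index votes tier``.
    ``true_times`` is ``NA`` when the fragment's true label is unknown. The file
    round-trips losslessly through :func:`read_localization`.
    """
    try:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(LOCALIZATION_COLUMNS)
            for res in results:
                tt = "NA" if res.true_times is None else res.true_times
                for idx, (votes, tier) in enumerate(zip(res.residue_votes, res.tiers)):
                    writer.writerow(
                        [res.fragment_id, res.predicted_label, tt, idx, int(votes), tier]
                    )
    except OSError as exc:
        raise OSError(f"failed to write localization table to {path}: {exc}") from exc


def read_localization(path: str | Path) -> list:
    """Read a localization TSV written by :func:`write_localization`."""
    from .localization import LocalizationResult  # deferred: avoids import cycle

    grouped: dict[str, dict] = {}
    order: list[str] = []
    for row in _read_tsv(path, LOCALIZATION_COLUMNS):
        fid = row["fragment_id"]
        if fid not in grouped:
            grouped[fid] = {
                "predicted_label": row["predicted_label"],
                "true_times": None
                if row["true_times"] == "NA"
                else int(row["true_times"]),
                "votes": [],
                "tiers": [],
            }
            order.append(fid)
        grouped[fid]["votes"].append(int(row["votes"]))
        grouped[fid]["tiers"].append(row["tier"])
    results = []
    for fid in order:
        g = grouped[fid]
        results.append(
            LocalizationResult(
                fragment_id=fid,
                predicted_label=g["predicted_label"],
                true_times=g["true_times"],
                dimer_votes=None,
                residue_votes=g["votes"],
                tiers=g["tiers"],
            )
        )
    return results


def _read_tsv(path: str | Path, expected_columns: Sequence[str]) -> Iterable[dict]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != tuple(
            expected_columns
        ):
            raise ValueError(
                f"{path}: expected columns {list(expected_columns)}, "
                f"found {reader.fieldnames}"
            )
        yield from reader
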