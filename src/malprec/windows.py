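"""Lysine-centered peptide window extraction.

Proteins are read from FASTA, candidate modification sites are 1-based
lysine positions, and each site is represented by a fixed-length peptide
window ``R[-n] ... R[-1] K R[+1] ... R[+eps]`` of length ``n + eps + 1``
(default 8 + 8 + 1 = 17).  Positions that fall outside the protein are
filled with the dummy residue ``X``, so every window has the same length
regardless of how close the lysine sits to a sequence terminus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy residue used to pad windows past the sequence ends.
PAD = "X"

#: Full 21-letter window alphabet (20 amino acids + X), fixed column order
#: for every encoder downstream.
ALPHABET = AA20 + PAD

# One-letter codes that occur in real FASTA files but are outside the
# 20-letter alphabet; mapped to X on input (B/Z ambiguity codes, J=I/L,
# U=selenocysteine, O=pyrrolysine, * stop).
_NONSTANDARD = set("BJOUZ*")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        # X is legal only as the residue left by input sanitation.
        bad = {c for c in self.sequence if c not in ALPHABET}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: residues outside the 21-letter "
                f"alphabet: {sorted(bad)} (run sanitize_sequence first)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate site: a 1-based residue position in a named protein.

    ``label`` is 1 for a malonylated lysine, 0 for a non-malonylated one,
    and None for an unlabeled candidate.
    """

    protein_id: str
    position: int
    label: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide fragment centered on a candidate lysine.

    ``residues`` has length ``n + eps + 1`` over the 21-letter alphabet;
    index ``n`` (0-based) is the center.  ``source`` records provenance as
    ``(protein_id, position)`` for real extractions or a free-form tag for
    synthetic windows.
    """

    residues: str
    n: int = 8
    eps: int = 8
    label: int | None = None
    source: tuple[str, int] | str | None = None

    def __post_init__(self) -> None:
        if len(self.residues) != self.n + self.eps + 1:
            raise ValueError(
                f"window length {len(self.residues)} != n+eps+1 = {self.n + self.eps + 1}"
            )
        bad = {c for c in self.residues if c not in ALPHABET}
        if bad:
            raise ValueError(f"window contains non-alphabet residues: {sorted(bad)}")

    @property
    def center(self) -> str:
        return self.residues[self.n]

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_sequence(seq: str, protein_id: str = "?") -> str:
    """Uppercase ``seq`` and map non-standard letters (B, J, O, U, Z, *) to X.

    The window alphabet has 20 native amino acids plus the dummy code X;
    anything else in the input is coerced to X with a logged warning.
    """
    seq = seq.upper()
    mapped = {c for c in seq if c not in AA20}
    if mapped:
        unknown = mapped - _NONSTANDARD - {PAD}
        if unknown:
            raise ValueError(
                f"protein {protein_id!r}: unrecognized characters {sorted(unknown)}"
            )
        logger.warning(
            "protein %s: mapping non-standard residues %s to X",
            protein_id,
            sorted(mapped),
        )
        seq = "".join(c if c in AA20 else PAD for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The identifier is the header token before the first whitespace;
    sequences are uppercased and non-standard letters mapped to X.
    Raises ``ValueError`` on an empty or malformed file.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA, first line is {first.strip()!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def extract_window(
    protein: ProteinRecord,
    position: int,
    n: int = 8,
    eps: int = 8,
    label: int | None = None,
    strict_center: bool = False,
) -> PeptideWindow:
    """Extract the window covering residues ``position-n .. position+eps``.

    ``position`` is 1-based.  Out-of-range flank positions are filled with
    X.  The center residue is expected to be lysine; a mismatch warns by
    default and raises in ``strict_center`` mode.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} out of range 1..{len(seq)} for protein {protein.id!r}"
        )
    center = seq[position - 1]
    if center != "K":
        msg = (
            f"protein {protein.id!r} position {position}: center residue "
            f"{center!r} is not lysine"
        )
        if strict_center:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    i0 = position - 1 - n  # 0-based inclusive start
    i1 = position - 1 + eps  # 0-based inclusive end
    left_pad = max(0, -i0)
    right_pad = max(0, i1 - (len(seq) - 1))
    core = seq[max(0, i0) : min(len(seq), i1 + 1)]
    residues = PAD * left_pad + core + PAD * right_pad
    return PeptideWindow(
        residues=residues,
        n=n,
        eps=eps,
        label=label,
        source=(protein.id, position),
    )


def extract_annotated_windows(
    proteins: Sequence[ProteinRecord],
    annotations: Iterable[SiteAnnotation],
    n: int = 8,
    eps: int = 8,
    strict_center: bool = False,
) -> list[PeptideWindow]:
    """Extract one labeled window per annotation, in annotation order."""
    annotations = list(annotations)
    index = {p.id: p for p in proteins}
    missing = sorted({a.protein_id for a in annotations} - index.keys())
    if missing:
        raise KeyError(f"annotations reference unknown proteins: {missing}")
    return [
        extract_window(
            index[a.protein_id], a.position, n=n, eps=eps, label=a.label,
            strict_center=strict_center,
        )
        for a in annotations
    ]


def enumerate_candidate_sites(protein: ProteinRecord) -> list[SiteAnnotation]:
    """List every lysine in the protein as an unlabeled candidate site."""
    return [
        SiteAnnotation(protein_id=protein.id, position=i + 1)
        for i, c in enumerate(protein.sequence)
        if c == "K"
    ]


# ---------------------------------------------------------------------------
# Plain-text I/O

ANNOTATION_HEADER = ["protein_id", "position", "label"]
WINDOW_HEADER = ["window", "label", "protein_id", "position"]


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV: protein_id <TAB> position <TAB> label."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATION_HEADER:
            raise ValueError(f"{path}: expected header {ANNOTATION_HEADER}, got {header}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            pid, pos, lab = parts
            label = None if lab in ("", "?") else int(lab)
            out.append(SiteAnnotation(protein_id=pid, position=int(pos), label=label))
    return out


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for a in annotations:
            lab = "?" if a.label is None else str(a.label)
            fh.write(f"{a.protein_id}\t{a.position}\t{lab}\n")


def write_windows(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as TSV: window <TAB> label <TAB> protein_id <TAB> position.

    Synthetic windows store their tag in the protein_id column with
    position 0.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_HEADER) + "\n")
        for w in windows:
            lab = "?" if w.label is None else str(w.label)
            if isinstance(w.source, tuple):
                pid, pos = w.source
            elif w.source is None:
                pid, pos = "", 0
            else:
                pid, pos = str(w.source), 0
            fh.write(f"{w.residues}\t{lab}\t{pid}\t{pos}\n")


def read_windows(path: str | Path, n: int = 8, eps: int = 8) -> list[PeptideWindow]:
    """Read a windows TSV written by :func:`write_windows`."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != WINDOW_HEADER:
            raise ValueError(f"{path}: expected header {WINDOW_HEADER}, got {header}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            res, lab, pid, pos = parts
            label = None if lab == "?" else int(lab)
            source: tuple[str, int] | str | None
            if int(pos) > 0:
                source = (pid, int(pos))
            elif pid:
                source = pid
            else:
                source = None
            out.append(PeptideWindow(residues=res, n=n, eps=eps, label=label, source=source))
    return out
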