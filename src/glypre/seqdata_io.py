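"""Readers, writers and dataset assembly for glycation-site data.

Formats handled: multi-record FASTA, AAindex1 flat files, PSIPRED
vertical ``.ss2`` output, and tab-separated site-annotation tables.
Positions in files are 1-based (UniProt convention); everything in
memory is 0-based.  The conversion happens in this module and nowhere
else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard residues, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Wildcard used for terminal padding and sanitized non-standard letters.
WILDCARD = "X"
ALPHABET = AA20 + WILDCARD
AA_TO_INT = {a: i for i, a in enumerate(ALPHABET)}
_AA20_SET = frozenset(AA20)

# Residue order of the two value rows in an AAindex1 entry:
# row 1 = A R N D C Q E G H I, row 2 = L K M F P S T W Y V.
_AAINDEX_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"


def sanitize_sequence(raw: str) -> str:
    """Uppercase and map non-standard letters (B, Z, U, O, J, ``*``...) to 'X'."""
    return "".join(
        c if c in _AA20_SET else WILDCARD
        for c in raw.upper()
        if not c.isspace()
    )


@dataclass(frozen=True)
class ProteinRecord:
    """A sanitized protein sequence over the 21-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record needs a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains letters outside the 21-letter "
                f"alphabet: {sorted(bad)}; sanitize first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One candidate lysine: protein accession, 1-based position, binary label."""

    protein_id: str
    position: int  # 1-based
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("annotation positions are 1-based (>= 1)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed odd-length residue string centred on a candidate site.

    ``source`` records (protein_id, 1-based centre position) so windows of
    other sizes can be re-extracted later.  The centre residue must be 'K'
    unless the window was built with ``relaxed=True``.
    """

    residues: str
    source: tuple[str, int] | None = None
    label: int | None = None
    relaxed: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0 or not self.residues:
            raise ValueError("window length must be odd")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"window contains invalid letters {sorted(bad)}")
        if not self.relaxed and self.center_residue != "K":
            raise ValueError(
                f"window centre is {self.center_residue!r}, expected 'K' "
                "(pass relaxed=True to override)"
            )

    @property
    def size(self) -> int:
        return len(self.residues)

    @property
    def center_index(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.center_index]


@dataclass(frozen=True)
class AAIndexTable:
    """A set of amino-acid property scales, one row per AAindex accession.

    ``values`` has shape (n_indices, 20) with columns in :data:`AA20` order.
    """

    accessions: tuple[str, ...]
    values: np.ndarray
    normalization: str = "raw"  # "raw" | "zscore"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.accessions), 20):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.accessions)} accessions x 20 residues"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("AAindex table contains non-finite values")
        object.__setattr__(self, "values", v)

    def zscored(self) -> "AAIndexTable":
        """Each index centred and scaled to unit variance over the 20 residues."""
        if self.normalization == "zscore":
            return self
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            flat = [a for a, s in zip(self.accessions, sd.ravel()) if s == 0]
            raise ValueError(f"cannot z-score constant indices: {flat}")
        return AAIndexTable(self.accessions, (self.values - mu) / sd, "zscore")

    def to_json_dict(self) -> dict:
        return {
            "schema": "glypre.aaindex.v1",
            "residue_order": AA20,
            "normalization": self.normalization,
            "accessions": list(self.accessions),
            "values": self.values.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "AAIndexTable":
        if d.get("schema") != "glypre.aaindex.v1":
            raise ValueError("unrecognised AAindex table schema")
        return cls(tuple(d["accessions"]), np.asarray(d["values"]),
                   d.get("normalization", "raw"))


@dataclass(frozen=True)
class SSProfile:
    """Per-residue secondary-structure probabilities in .ss2 column order (C, H, E)."""

    probs: np.ndarray  # (L, 3)
    residues: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("SS profile must have shape (L, 3)")
        if np.any(p < 0):
            raise ValueError("SS probabilities must be non-negative")
        sums = p.sum(axis=1)
        if np.any((sums < 0.95) | (sums > 1.05)):
            bad = int(np.argmax((sums < 0.95) | (sums > 1.05)))
            raise ValueError(
                f"SS probability triple at residue {bad + 1} sums to "
                f"{sums[bad]:.4f}, outside [0.95, 1.05]"
            )
        object.__setattr__(self, "probs", p)
        if self.residues is not None and len(self.residues) != len(p):
            raise ValueError("residue string length does not match profile")

    def __len__(self) -> int:
        return len(self.probs)

    def normalized(self) -> np.ndarray:
        """Rows rescaled to sum exactly 1 (the form encoders consume)."""
        return self.probs / self.probs.sum(axis=1, keepdims=True)


@dataclass
class LabelledDataset:
    """Aligned windows + labels, with the achieved class ratio and draw seed."""

    windows: list[PeptideWindow]
    labels: np.ndarray
    class_ratio: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels are not aligned")
        sites = [w.source for w in self.windows]
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate (protein_id, position) pairs in dataset")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return [w.source for w in self.windows]

    def windows_at(self, proteins_by_id: Mapping[str, ProteinRecord],
                   size: int) -> list[PeptideWindow]:
        """Re-extract every window at another odd size from the source proteins."""
        return [
            extract_window(proteins_by_id[pid], pos, size)
            for pid, pos in self.sites
        ]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA, sanitizing sequences to the 21-letter alphabet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path), "fasta",
    )


def proteins_by_id(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    out: dict[str, ProteinRecord] = {}
    for r in records:
        if r.id in out:
            raise ValueError(f"duplicate protein id {r.id!r}")
        out[r.id] = r
    return out


# ---------------------------------------------------------------------------
# AAindex1


def read_aaindex1(path: str | Path, accessions: Sequence[str],
                  zscore: bool = False) -> AAIndexTable:
    """Read selected entries from an AAindex1 flat file.

    The flat-file layout is: an ``H`` line with the accession, an ``I``
    header line naming the residue order, two continuation rows of ten
    values each, and ``//`` terminating the entry.  ``NA`` cells are
    imputed with the mean of that index's available values.
    """
    entries: dict[str, np.ndarray] = {}
    acc = None
    collecting = False
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                acc = line.split()[1]
                collecting = False
                tokens = []
            elif line.startswith("I "):
                collecting = True
            elif line.startswith("//"):
                if acc is not None and tokens:
                    entries[acc] = _aaindex_values(acc, tokens)
                acc = None
                collecting = False
                tokens = []
            elif collecting and (line.startswith(" ") or line.startswith("\t")):
                tokens.extend(line.split())
            elif collecting:
                collecting = False
    missing = [a for a in accessions if a not in entries]
    if missing:
        raise ValueError(f"accessions not found in AAindex file: {missing}")
    values = np.stack([entries[a] for a in accessions])
    table = AAIndexTable(tuple(accessions), values, "raw")
    return table.zscored() if zscore else table


def _aaindex_values(acc: str, tokens: list[str]) -> np.ndarray:
    if len(tokens) != 20:
        raise ValueError(f"AAindex entry {acc} has {len(tokens)} values, expected 20")
    row = np.array([np.nan if t == "NA" else float(t) for t in tokens])
    if np.all(np.isnan(row)):
        raise ValueError(f"AAindex entry {acc} has no usable values")
    if np.any(np.isnan(row)):
        row = np.where(np.isnan(row), np.nanmean(row), row)
    # Reorder from the flat-file residue order to AA20 (alphabetical) order.
    out = np.empty(20)
    for value, residue in zip(row, _AAINDEX_ROW_ORDER):
        out[AA_TO_INT[residue]] = value
    return out


# ---------------------------------------------------------------------------
# PSIPRED .ss2


def read_psipred_ss2(path: str | Path, sequence: str | None = None) -> SSProfile:
    """Read a PSIPRED vertical-format file into an :class:`SSProfile`.

    Data rows look like ``1 M C 0.700 0.200 0.100`` with the probability
    columns in coil/helix/strand order.  If ``sequence`` is given, residue
    letters and row count are checked against it.
    """
    rows: list[tuple[float, float, float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            try:
                triple = (float(parts[3]), float(parts[4]), float(parts[5]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric probability"
                ) from exc
            rows.append(triple)
            residues.append(parts[1])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    profile = SSProfile(np.array(rows), "".join(residues))
    if sequence is not None:
        if len(profile) != len(sequence):
            raise ValueError(
                f"{path}: {len(profile)} rows but sequence has {len(sequence)} residues"
            )
        for i, (a, b) in enumerate(zip(profile.residues, sequence)):
            if a != b and WILDCARD not in (a, b):
                raise ValueError(
                    f"{path}: residue mismatch at position {i + 1}: "
                    f"{a!r} vs sequence {b!r}"
                )
    return profile


_SS_LETTERS = "CHE"


def write_psipred_ss2(profile: SSProfile, path: str | Path,
                      sequence: str | None = None) -> None:
    """Write an :class:`SSProfile` in PSIPRED vertical format."""
    seq = sequence or profile.residues
    if seq is None:
        seq = WILDCARD * len(profile)
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (res, row) in enumerate(zip(seq, profile.probs), start=1):
            letter = _SS_LETTERS[int(np.argmax(row))]
            fh.write(f"{i:4d} {res} {letter}   {row[0]:.3f}  {row[1]:.3f}  {row[2]:.3f}\n")


# ---------------------------------------------------------------------------
# Site annotations


def read_site_annotations(path: str | Path) -> list[SiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "label"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        SiteAnnotation(str(r.protein_id), int(r.position), int(r.label))
        for r in df.itertuples()
    ]


def write_site_annotations(annotations: Iterable[SiteAnnotation],
                           path: str | Path) -> None:
    pd.DataFrame(
        [(a.protein_id, a.position, a.label) for a in annotations],
        columns=["protein_id", "position", "label"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Window extraction and dataset assembly


def extract_window(protein: ProteinRecord, position: int, size: int,
                   relax_center: bool = False, label: int | None = None
                   ) -> PeptideWindow:
    """Extract the odd-length window centred at a 1-based position.

    Flanks that run past either terminus are padded with 'X' so the window
    always has exactly ``size`` residues.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"window size must be odd and positive, got {size}")
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} outside protein {protein.id!r} "
            f"(length {len(protein)})"
        )
    half = (size - 1) // 2
    center = position - 1
    lo, hi = center - half, center + half + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(protein))
    core = protein.sequence[max(0, lo):min(hi, len(protein))]
    residues = WILDCARD * left_pad + core + WILDCARD * right_pad
    return PeptideWindow(residues, source=(protein.id, position), label=label,
                         relaxed=relax_center)


def build_dataset(proteins: Sequence[ProteinRecord],
                  annotations: Sequence[SiteAnnotation],
                  window_size: int = 31,
                  neg_per_pos: float = 2.0,
                  seed: int = 0) -> LabelledDataset:
    """Assemble the labelled window dataset.

    Positives are the annotated glycation lysines (label 1).  The negative
    pool is every other lysine in the proteins — including sites explicitly
    annotated with label 0 — from which ``neg_per_pos x n_positives`` are
    drawn without replacement using ``seed``.  The positive set never
    depends on the seed.
    """
    if neg_per_pos <= 0:
        raise ValueError("neg_per_pos must be positive")
    by_id = proteins_by_id(proteins)

    pos_sites: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for ann in annotations:
        if ann.protein_id not in by_id:
            raise ValueError(f"annotation references unknown protein {ann.protein_id!r}")
        prot = by_id[ann.protein_id]
        if not 1 <= ann.position <= len(prot):
            raise ValueError(
                f"annotation position {ann.position} outside protein "
                f"{ann.protein_id!r}"
            )
        if prot.sequence[ann.position - 1] != "K":
            raise ValueError(
                f"annotated residue at {ann.protein_id}:{ann.position} is "
                f"{prot.sequence[ann.position - 1]!r}, expected 'K'"
            )
        key = (ann.protein_id, ann.position)
        if key in seen:
            raise ValueError(f"duplicate annotation for {key}")
        seen.add(key)
        if ann.label == 1:
            pos_sites.append(key)
    if not pos_sites:
        raise ValueError("no positive annotations")

    pos_set = set(pos_sites)
    pool = [
        (p.id, i + 1)
        for p in proteins
        for i, c in enumerate(p.sequence)
        if c == "K" and (p.id, i + 1) not in pos_set
    ]
    n_neg = int(round(neg_per_pos * len(pos_sites)))
    rng = np.random.default_rng(seed)
    if len(pool) < n_neg:
        warnings.warn(
            f"negative pool has only {len(pool)} lysines; requested {n_neg}; "
            "taking the whole pool",
            stacklevel=2,
        )
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n_neg, replace=False)
        chosen = [pool[i] for i in sorted(idx)]

    windows = [
        extract_window(by_id[pid], pos, window_size, label=1)
        for pid, pos in pos_sites
    ] + [
        extract_window(by_id[pid], pos, window_size, label=0)
        for pid, pos in chosen
    ]
    labels = np.array([1] * len(pos_sites) + [0] * len(chosen))
    return LabelledDataset(windows, labels, len(chosen) / len(pos_sites), seed)


# ---------------------------------------------------------------------------
# Redundancy filtering (approximate CD-HIT stand-in)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


def greedy_redundancy_filter(proteins: Sequence[ProteinRecord],
                             identity_threshold: float = 0.3
                             ) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal by global-alignment identity.

    This approximates clustering tools such as CD-HIT; it is quadratic in
    the number of sequences and intended for small corpora only.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    ordered = sorted(proteins, key=lambda p: (-len(p), p.id))
    kept: list[ProteinRecord] = []
    for cand in ordered:
        # Exact duplicates are always redundant, even at threshold 1.0.
        if all(
            cand.sequence != k.sequence
            and pairwise_identity(cand.sequence, k.sequence) <= identity_threshold
            for k in kept
        ):
            kept.append(cand)
    order = {p.id: i for i, p in enumerate(proteins)}
    kept.sort(key=lambda p: order[p.id])
    return kept
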