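"""The four feature groups used to encode a candidate lysine.

* position scoring function — a pseudocounted position weight matrix fit on
  positive windows, scored as ``F(l) = ln(P_xl / p0) * (Mp(l) - MN(l))``
  where ``Mp``/``MN`` are the per-position conservation statistics of the
  positive and negative classes and ``p0 = 0.05`` is the uniform background;
* secondary structure — per-residue coil/helix/strand probabilities from a
  PSIPRED-style profile;
* AAindex — physicochemical property values of each window residue, z-scored
  per index over the 20 amino acids;
* CKSAAP — compositions of k-spaced amino-acid pairs over the 21-letter
  alphabet, with an information-gain-selected top-m projection.

Each group extracts its own window size around the same centre; the default
sizes (31, 27, 13, 25) concatenate to the 402-dimensional vector
31 + 27*3 + 13*20 + 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqdata_io import (
    AA20,
    AA_TO_INT,
    ALPHABET,
    WILDCARD,
    AAIndexTable,
    PeptideWindow,
    ProteinRecord,
    SSProfile,
    extract_window,
)

_X_CODE = len(AA20)  # 20
BACKGROUND_P0 = 0.05


# ---------------------------------------------------------------------------
# Configuration and layout


@dataclass(frozen=True)
class EncoderConfig:
    """Window sizes and dimensions of the four feature groups.

    Defaults are the per-group optima of the predictor: 31 (position scores),
    27 (secondary structure), 13 (AAindex) and 25 (CKSAAP), with pair gaps
    k = 0..4 and a top-30 CKSAAP projection.
    """

    window_pssf: int = 31
    window_ss: int = 27
    window_aaindex: int = 13
    window_cksaap: int = 25
    k_max: int = 4
    top_m_cksaap: int = 30
    use_pssf: bool = True
    use_ss: bool = True
    use_aaindex: bool = True
    use_cksaap: bool = True
    p0: float = BACKGROUND_P0

    def __post_init__(self) -> None:
        for name in ("window_pssf", "window_ss", "window_aaindex", "window_cksaap"):
            w = getattr(self, name)
            if w % 2 == 0 or not 11 <= w <= 31:
                raise ValueError(f"{name}={w}: window sizes must be odd and in [11, 31]")
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")
        if self.top_m_cksaap < 1:
            raise ValueError("top_m_cksaap must be >= 1")
        if self.window_cksaap <= self.k_max + 1:
            raise ValueError("CKSAAP window too short for k_max")
        if not (self.use_pssf or self.use_ss or self.use_aaindex or self.use_cksaap):
            raise ValueError("at least one feature group must be enabled")


@dataclass(frozen=True)
class FeatureBlock:
    name: str
    start: int
    labels: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.labels)

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class FeatureLayout:
    """Named, contiguous, non-overlapping blocks of the assembled vector."""

    blocks: tuple[FeatureBlock, ...]

    def __post_init__(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValueError(f"block {b.name!r} starts at {b.start}, expected {pos}")
            pos = b.stop

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def labels(self) -> list[str]:
        return [lab for b in self.blocks for lab in b.labels]

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def slice(self, name: str) -> slice:
        b = self.block(name)
        return slice(b.start, b.stop)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: FeatureLayout

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.layout.total_length,):
            raise ValueError(
                f"vector length {v.shape} does not match layout "
                f"({self.layout.total_length})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def _offsets(window: int) -> list[int]:
    half = (window - 1) // 2
    return list(range(-half, half + 1))


def build_layout(config: EncoderConfig,
                 accessions: Sequence[str] | None = None,
                 selected_pairs: Sequence[tuple[int, str]] | None = None
                 ) -> FeatureLayout:
    """Layout of the concatenation PSSF | SS | AAindex | CKSAAP-top."""
    blocks: list[FeatureBlock] = []
    pos = 0
    if config.use_pssf:
        labels = tuple(f"PSSF:pos={o:+d}" for o in _offsets(config.window_pssf))
        blocks.append(FeatureBlock("pssf", pos, labels))
        pos += len(labels)
    if config.use_ss:
        labels = tuple(
            f"SS:pos={o:+d}:{s}"
            for o in _offsets(config.window_ss)
            for s in "CHE"
        )
        blocks.append(FeatureBlock("ss", pos, labels))
        pos += len(labels)
    if config.use_aaindex:
        if accessions is None:
            raise ValueError("AAindex group enabled but no accessions given")
        labels = tuple(
            f"AAI:{acc}:pos={o:+d}"
            for acc in accessions
            for o in _offsets(config.window_aaindex)
        )
        blocks.append(FeatureBlock("aaindex", pos, labels))
        pos += len(labels)
    if config.use_cksaap:
        if selected_pairs is None:
            raise ValueError("CKSAAP group enabled but no selected pairs given")
        labels = tuple(cksaap_pair_label(k, pair) for k, pair in selected_pairs)
        blocks.append(FeatureBlock("cksaap", pos, labels))
    return FeatureLayout(tuple(blocks))


# ---------------------------------------------------------------------------
# Windows as integer matrices


def windows_to_ints(windows: Sequence[PeptideWindow | str]) -> np.ndarray:
    """Stack windows into an (n, W) int matrix; 'X' maps to code 20."""
    strings = [w.residues if isinstance(w, PeptideWindow) else w for w in windows]
    if not strings:
        raise ValueError("no windows")
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise ValueError(f"ragged window lengths: {sorted(lengths)}")
    return np.array([[AA_TO_INT[c] for c in s] for s in strings], dtype=np.int64)


# ---------------------------------------------------------------------------
# Position scoring function


def column_frequencies(windows: Sequence[PeptideWindow | str], l: int) -> np.ndarray:
    """Occurrence frequencies of the 20 residues at column ``l``.

    'X' is excluded from the denominator; an all-'X' column yields zeros.
    """
    mat = windows_to_ints(windows)
    col = mat[:, l]
    col = col[col != _X_CODE]
    if col.size == 0:
        return np.zeros(20)
    return np.bincount(col, minlength=20) / col.size


def conservation_M(freqs: np.ndarray, p0: float = BACKGROUND_P0) -> float:
    """Chi-square-style conservation of a residue-frequency column.

    Zero iff the 20 frequencies all equal the background ``p0``; larger
    values mean stronger positional preference.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    return float(np.sum((freqs - p0) ** 2) / p0)


@dataclass(frozen=True)
class PWMModel:
    """Pseudocounted position weight matrix plus class conservation vectors.

    ``P`` is (20, W) with rows in :data:`AA20` order; each column sums to 1.
    ``P_xl = (n_xl + p0*sqrt(N_l)) / (N_l + sqrt(N_l))`` where ``n_xl`` counts
    residue x among the N_l non-'X' positive residues at column l — the
    square-root pseudocount whose columns sum to exactly 1 because
    ``20 * p0 = 1``.  ``Mp``/``MN`` hold the per-column conservation of the
    positive and negative training windows.
    """

    W: int
    P: np.ndarray
    Mp: np.ndarray
    MN: np.ndarray
    p0: float
    N: int

    def __post_init__(self) -> None:
        if self.P.shape != (20, self.W):
            raise ValueError("PWM must be 20 x W")
        if not np.allclose(self.P.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.Mp < 0) or np.any(self.MN < 0):
            raise ValueError("conservation vectors must be non-negative")

    def to_json_dict(self) -> dict:
        return {
            "schema": "glypre.pwm.v1",
            "residue_order": AA20,
            "W": self.W,
            "P": self.P.tolist(),  # rows = residues (AA20 order), cols = positions
            "Mp": self.Mp.tolist(),
            "MN": self.MN.tolist(),
            "p0": self.p0,
            "N": self.N,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "PWMModel":
        if d.get("schema") != "glypre.pwm.v1":
            raise ValueError("unrecognised PWM schema")
        return cls(int(d["W"]), np.asarray(d["P"]), np.asarray(d["Mp"]),
                   np.asarray(d["MN"]), float(d["p0"]), int(d["N"]))


def fit_pwm(positives: Sequence[PeptideWindow | str],
            negatives: Sequence[PeptideWindow | str],
            p0: float = BACKGROUND_P0) -> PWMModel:
    """Fit the PWM on positive windows and both conservation vectors."""
    if not len(positives):
        raise ValueError("cannot fit a PWM on an empty positive set")
    if not len(negatives):
        raise ValueError("negative windows are required for MN(l)")
    pos = windows_to_ints(positives)
    neg = windows_to_ints(negatives)
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("positive and negative windows have different lengths")
    W = pos.shape[1]

    P = np.empty((20, W))
    Mp = np.empty(W)
    MN = np.empty(W)
    for l in range(W):
        col = pos[:, l]
        col = col[col != _X_CODE]
        n_l = col.size
        if n_l == 0:
            P[:, l] = p0
            Mp[l] = conservation_M(np.zeros(20), p0)
        else:
            counts = np.bincount(col, minlength=20)
            root = np.sqrt(n_l)
            P[:, l] = (counts + p0 * root) / (n_l + root)
            Mp[l] = conservation_M(counts / n_l, p0)
        MN[l] = conservation_M(column_frequencies(negatives, l), p0)
    return PWMModel(W, P, Mp, MN, p0, len(positives))


def encode_position_scores(window: PeptideWindow | str, pwm: PWMModel) -> np.ndarray:
    """Per-position score ``ln(P_xl / p0) * (Mp(l) - MN(l))``; 'X' scores 0."""
    return position_scores_matrix(windows_to_ints([window]), pwm)[0]


def position_scores_matrix(int_mat: np.ndarray, pwm: PWMModel) -> np.ndarray:
    """Vectorized position scores for an (n, W) integer window matrix."""
    if int_mat.shape[1] != pwm.W:
        raise ValueError(
            f"window length {int_mat.shape[1]} does not match PWM ({pwm.W})"
        )
    logratio = np.vstack([np.log(pwm.P / pwm.p0), np.zeros(pwm.W)])  # 'X' row -> 0
    weight = pwm.Mp - pwm.MN
    cols = np.arange(pwm.W)
    return logratio[int_mat, cols] * weight


# ---------------------------------------------------------------------------
# Secondary structure


def encode_ss(profile: SSProfile, center: int, window_ss: int) -> np.ndarray:
    """Flattened (C, H, E) triples for the window around residue ``center``.

    ``center`` is a 0-based residue index.  In-chain triples are renormalized
    to sum 1; positions beyond either terminus encode (0, 0, 0) to mark
    missing structure.
    """
    if window_ss % 2 == 0 or window_ss < 1:
        raise ValueError("window_ss must be odd")
    if not 0 <= center < len(profile):
        raise ValueError(f"centre {center} outside protein of length {len(profile)}")
    half = (window_ss - 1) // 2
    norm = profile.normalized()
    out = np.zeros((window_ss, 3))
    for i, j in enumerate(range(center - half, center + half + 1)):
        if 0 <= j < len(profile):
            out[i] = norm[j]
    return out.ravel()


# ---------------------------------------------------------------------------
# AAindex


def encode_aaindex(window: PeptideWindow | str, table: AAIndexTable) -> np.ndarray:
    """Index-major physicochemical encoding; 'X' positions encode 0.

    With a z-scored table, 0 is the per-index mean over the 20 residues, so
    padding is neutral.
    """
    mat = windows_to_ints([window])[0]
    W = mat.size
    # Append a zero column for the 'X' code.
    values = np.hstack([table.values, np.zeros((len(table.accessions), 1))])
    out = values[:, mat]  # (n_indices, W)
    return out.reshape(len(table.accessions) * W)


# ---------------------------------------------------------------------------
# CKSAAP


def cksaap_pair_label(k: int, pair: str) -> str:
    return f"CKSAAP:k={k}:{pair[0]}{'x' * k}{pair[1]}"


def cksaap_pairs(k_max: int = 4) -> list[tuple[int, str]]:
    """The (k, pair) universe in vector order: k-major, then first residue, then second."""
    return [
        (k, a + b)
        for k in range(k_max + 1)
        for a in ALPHABET
        for b in ALPHABET
    ]


def cksaap_pair_index(k: int, pair: str, k_max: int = 4) -> int:
    if not (0 <= k <= k_max):
        raise ValueError(f"k={k} outside 0..{k_max}")
    if len(pair) != 2 or any(c not in AA_TO_INT for c in pair):
        raise ValueError(f"invalid residue pair {pair!r}")
    n = len(ALPHABET)
    return k * n * n + AA_TO_INT[pair[0]] * n + AA_TO_INT[pair[1]]


def cksaap_matrix(windows: Sequence[PeptideWindow | str], k_max: int = 4) -> np.ndarray:
    """(n, 441*(k_max+1)) compositions of k-spaced ordered residue pairs.

    For gap k, the pair at (i, i+k+1) is counted over all valid i and the
    counts are divided by W-k-1, so each per-k block is a composition
    summing to 1.
    """
    mat = windows_to_ints(windows)
    n, W = mat.shape
    if W <= k_max + 1:
        raise ValueError(f"window length {W} too short for k_max={k_max}")
    m = len(ALPHABET)
    blocks = []
    rows_all = np.arange(n)
    for k in range(k_max + 1):
        npairs = W - k - 1
        pair_codes = mat[:, :npairs] * m + mat[:, k + 1:]
        counts = np.zeros((n, m * m))
        np.add.at(
            counts,
            (np.repeat(rows_all, npairs), pair_codes.ravel()),
            1.0,
        )
        blocks.append(counts / npairs)
    return np.hstack(blocks)


def encode_cksaap_full(window: PeptideWindow | str, k_max: int = 4) -> np.ndarray:
    return cksaap_matrix([window], k_max)[0]


def encode_cksaap_top(window: PeptideWindow | str,
                      selected_pairs: Sequence[tuple[int, str]],
                      k_max: int = 4) -> np.ndarray:
    """The selected (k, pair) compositions in ranking order."""
    full = encode_cksaap_full(window, k_max)
    idx = [cksaap_pair_index(k, pair, k_max) for k, pair in selected_pairs]
    return full[idx]


def pairs_from_indices(indices: Sequence[int], k_max: int = 4) -> list[tuple[int, str]]:
    """Map flat CKSAAP vector indices back to (k, pair) tuples."""
    universe = cksaap_pairs(k_max)
    return [universe[i] for i in indices]


# ---------------------------------------------------------------------------
# Assembly


def assemble(protein: ProteinRecord,
             position: int,
             config: EncoderConfig,
             pwm: PWMModel | None = None,
             table: AAIndexTable | None = None,
             profile: SSProfile | None = None,
             selected_pairs: Sequence[tuple[int, str]] | None = None,
             relax_center: bool = False) -> FeatureVector:
    """Concatenated feature vector for the lysine at a 1-based position.

    Each enabled group extracts its own window size around the same centre.
    Default configuration: 31 + 81 + 260 + 30 = 402 dimensions.
    """
    parts: list[np.ndarray] = []
    if config.use_pssf:
        if pwm is None:
            raise ValueError("position-score group enabled but no PWM given")
        w = extract_window(protein, position, config.window_pssf,
                           relax_center=relax_center)
        parts.append(encode_position_scores(w, pwm))
    if config.use_ss:
        if profile is None:
            raise ValueError(
                f"secondary-structure group enabled but no profile for "
                f"{protein.id!r}"
            )
        parts.append(encode_ss(profile, position - 1, config.window_ss))
    if config.use_aaindex:
        if table is None:
            raise ValueError("AAindex group enabled but no table given")
        w = extract_window(protein, position, config.window_aaindex,
                           relax_center=relax_center)
        parts.append(encode_aaindex(w, table.zscored()))
    if config.use_cksaap:
        if selected_pairs is None:
            raise ValueError("CKSAAP group enabled but no selected pairs given")
        w = extract_window(protein, position, config.window_cksaap,
                           relax_center=relax_center)
        parts.append(encode_cksaap_top(w, selected_pairs, config.k_max))
    layout = build_layout(
        config,
        accessions=table.accessions if (config.use_aaindex and table) else None,
        selected_pairs=selected_pairs,
    )
    return FeatureVector(np.concatenate(parts), layout)
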