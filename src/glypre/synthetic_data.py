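"""Synthetic corpora with the statistical structure of glycation data.

The generator emulates the two signals the predictor is built to detect:

* positional residue enrichment — alanine, glutamate and leucine boosted at
  offsets -6 and +4 of positive (glycated) lysines, against a uniform
  background;
* a helix-biased secondary-structure profile within a few residues of
  positive sites, coil-biased elsewhere.

Negatives are the background lysines that arise by chance.  Everything is
reproducible from a single seed, and the emitted files are exactly the
formats the I/O module reads (FASTA, annotation TSV, .ss2, AAindex1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqdata_io import (
    AA20,
    AA_TO_INT,
    AAIndexTable,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
    SSProfile,
    read_aaindex1,
    write_fasta,
    write_psipred_ss2,
    write_site_annotations,
)

#: Approximate Swiss-Prot residue composition, AA20 (alphabetical) order.
NATURAL_FREQUENCIES = np.array([
    0.0825, 0.0137, 0.0545, 0.0675, 0.0386, 0.0707, 0.0227, 0.0596, 0.0584,
    0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0656, 0.0534, 0.0687,
    0.0108, 0.0292,
])
NATURAL_FREQUENCIES = NATURAL_FREQUENCIES / NATURAL_FREQUENCIES.sum()


def background_frequencies(kind: str = "uniform") -> np.ndarray:
    """Residue background: 'uniform' (0.05 each, matching the p0 of the
    scoring function) or 'natural' (Swiss-Prot-like composition)."""
    if kind == "uniform":
        return np.full(20, 0.05)
    if kind == "natural":
        return NATURAL_FREQUENCIES.copy()
    raise ValueError(f"unknown background kind {kind!r}")


@dataclass(frozen=True)
class MotifSpec:
    """Positional residue enrichment around positive sites.

    ``effect_size`` is the total probability mass moved onto the enriched
    residues at each listed offset, split equally among them; the remaining
    residues are scaled down to keep the distribution normalized.  With the
    defaults (A/E/L at -6 and +4, effect 0.35) each enriched residue reaches
    a frequency of about 0.167 — comfortably above the >10% enrichment the
    predictor is meant to pick up.  ``effect_size=0`` is the null model.
    """

    enriched: Mapping[int, str] = field(
        default_factory=lambda: {-6: "AEL", 4: "AEL"})
    effect_size: float = 0.35
    background: np.ndarray = field(
        default_factory=lambda: background_frequencies("uniform"))

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 20-vector summing to 1")
        if not 0 <= self.effect_size < 0.9:
            raise ValueError("effect_size must be in [0, 0.9)")
        for off, residues in self.enriched.items():
            if off == 0:
                raise ValueError("offset 0 is the lysine centre itself")
            if not residues or any(r not in AA20 for r in residues):
                raise ValueError(f"invalid enriched residues at {off}: {residues!r}")
        object.__setattr__(self, "background", bg)

    def position_distribution(self, offset: int) -> np.ndarray:
        """Residue distribution at an offset relative to a positive centre."""
        p = self.background.copy()
        residues = self.enriched.get(offset)
        if not residues or self.effect_size == 0:
            return p
        boost_idx = [AA_TO_INT[r] for r in residues]
        others = np.ones(20, dtype=bool)
        others[boost_idx] = False
        add = self.effect_size / len(boost_idx)
        target = p[boost_idx] + add
        p[others] *= (1.0 - target.sum()) / p[others].sum()
        p[boost_idx] = target
        return p


@dataclass(frozen=True)
class SyntheticConfig:
    """Corpus dimensions and secondary-structure bias.

    Defaults give 70 proteins x 3 sites = 210 positive lysines — the scale
    of the benchmark this emulates — with a 1:2 positive:negative split
    downstream.  Every lysine in a synthetic protein is planted: positives
    carry the motif, ``negatives_per_protein`` lysines per protein carry
    background flanks and form the negative pool, and the inter-residue
    background is lysine-free so no lysine ever sits inside another
    window's signal zone.  ``helix_bias`` is probability mass moved from
    coil to helix in the mean SS profile within ``helix_halfwidth``
    residues of a positive site; ``ss_concentration`` controls Dirichlet
    noise around those means.
    """

    n_proteins: int = 70
    length_range: tuple[int, int] = (280, 360)
    positives_per_protein: int = 3
    negatives_per_protein: int | None = None  # default: 2x positives + 1
    neg_per_pos: float = 2.0
    helix_bias: float = 0.20
    ss_concentration: float = 8.0
    helix_halfwidth: int = 6
    margin: int = 16
    min_spacing: int = 22
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.positives_per_protein < 1:
            raise ValueError("counts must be positive")
        if self.negatives_per_protein is None:
            object.__setattr__(self, "negatives_per_protein",
                               2 * self.positives_per_protein + 1)
        if self.negatives_per_protein < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.helix_bias <= 0.5:
            raise ValueError("helix_bias must be in [0, 0.5]")
        lo = self.length_range[0]
        needed = 2 * self.margin + self.sites_per_protein * self.min_spacing
        if lo < needed:
            raise ValueError(
                f"minimum protein length {lo} too short to host "
                f"{self.sites_per_protein} windows (need >= {needed})"
            )

    @property
    def sites_per_protein(self) -> int:
        return self.positives_per_protein + self.negatives_per_protein


# Mean (C, H, E) profile away from / near positive sites.
_SS_BASE = np.array([0.55, 0.25, 0.20])


@dataclass
class SyntheticCorpus:
    proteins: list[ProteinRecord]
    annotations: list[SiteAnnotation]
    profiles: dict[str, SSProfile]
    config: SyntheticConfig
    motif: MotifSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit proteins.fasta, annotations.tsv and ss2/<id>.ss2."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "proteins.fasta"
        ann = outdir / "annotations.tsv"
        ss2dir = outdir / "ss2"
        ss2dir.mkdir(exist_ok=True)
        write_fasta(self.proteins, fasta)
        write_site_annotations(self.annotations, ann)
        for prot in self.proteins:
            write_psipred_ss2(self.profiles[prot.id], ss2dir / f"{prot.id}.ss2",
                              sequence=prot.sequence)
        return {"fasta": fasta, "annotations": ann, "ss2_dir": ss2dir}


def generate_corpus(cfg: SyntheticConfig,
                    motif: MotifSpec | None = None) -> SyntheticCorpus:
    """Generate proteins, positive-site annotations and SS profiles.

    Every lysine is planted at a controlled location: positive sites get
    motif-boosted flanks at the enriched offsets, negative sites keep pure
    background flanks, and the remaining background is drawn from a
    lysine-free distribution.  Sites are spaced at least ``min_spacing``
    apart and kept ``margin`` residues from the termini, so no window of
    one site reaches another site's enriched positions (or its helix zone),
    and neither class is identifiable through terminal padding or incidental
    lysine pairs — the classes differ only in the planted signal.  Positive
    and negative roles are shuffled over the site slots per protein.  SS
    probabilities are Dirichlet draws around a helix-biased mean near
    positive sites and a coil-biased mean elsewhere.  Byte-identical output
    for identical seeds.
    """
    motif = motif if motif is not None else MotifSpec(
        background=background_frequencies(cfg.background))
    rng = np.random.default_rng(cfg.seed)
    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    profiles: dict[str, SSProfile] = {}
    aa = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")
    k_code = AA_TO_INT["K"]

    def _without_k(p: np.ndarray) -> np.ndarray:
        q = p.copy()
        q[k_code] = 0.0
        return q / q.sum()

    bg_no_k = _without_k(motif.background)
    flank_dists = {off: _without_k(motif.position_distribution(off))
                   for off in motif.enriched}

    for pi in range(cfg.n_proteins):
        pid = f"SYNP{pi + 1:04d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq_codes = rng.choice(20, size=L, p=bg_no_k)

        # One site per equal-width chunk, jittered so consecutive sites stay
        # at least min_spacing apart; positive/negative roles shuffled.
        n_sites = cfg.sites_per_protein
        usable = L - 2 * cfg.margin
        width = usable // n_sites
        sites = []
        for s in range(n_sites):
            jitter_max = max(1, width - cfg.min_spacing + 1)
            off = int(rng.integers(0, jitter_max))
            sites.append(cfg.margin + s * width + off)
        roles = rng.permutation(
            [1] * cfg.positives_per_protein + [0] * cfg.negatives_per_protein)

        pos_sites = []
        for site, role in zip(sites, roles):
            seq_codes[site] = k_code
            if role == 1:
                pos_sites.append(site)
                for offset, dist in flank_dists.items():
                    seq_codes[site + offset] = rng.choice(20, p=dist)
        sequence = "".join(aa[seq_codes])
        proteins.append(ProteinRecord(pid, sequence))
        annotations.extend(
            SiteAnnotation(pid, site + 1, 1) for site in pos_sites)

        near = np.zeros(L, dtype=bool)
        for site in pos_sites:
            lo = max(0, site - cfg.helix_halfwidth)
            hi = min(L, site + cfg.helix_halfwidth + 1)
            near[lo:hi] = True
        means = np.where(
            near[:, None],
            _SS_BASE + np.array([-cfg.helix_bias, cfg.helix_bias, 0.0]),
            _SS_BASE,
        )
        gamma = rng.standard_gamma(cfg.ss_concentration * means)
        gamma = np.maximum(gamma, 1e-12)
        probs = gamma / gamma.sum(axis=1, keepdims=True)
        profiles[pid] = SSProfile(probs, sequence)
    return SyntheticCorpus(proteins, annotations, profiles, cfg, motif)


# ---------------------------------------------------------------------------
# AAindex fixture


_AAINDEX_ROW_ORDER = "ARNDCQEGHILKMFPSTWYV"


def generate_aaindex_fixture(n_indices: int = 20, seed: int = 0,
                             n_na: int = 0) -> tuple[str, list[str]]:
    """An AAindex1-format flat file with standard-normal synthetic scales.

    Returns (file text, accession list).  The first ``n_na`` indices carry
    one ``NA`` cell each, to exercise missing-value imputation.  Identical
    seeds give identical text.
    """
    if n_indices < 1:
        raise ValueError("need at least one index")
    rng = np.random.default_rng(seed)
    accessions = [f"SYNT{i + 1:03d}101" for i in range(n_indices)]
    lines: list[str] = []
    for i, acc in enumerate(accessions):
        values = np.round(rng.standard_normal(20), 3)
        cells = [f"{v:7.3f}" for v in values]
        if i < n_na:
            cells[i % 20] = f"{'NA':>7}"
        lines.append(f"H {acc}")
        lines.append(f"D Synthetic physicochemical scale {i + 1} "
                     "(standard-normal values; synthetic fixture)")
        lines.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     "
                     "E/T     G/W     H/Y     I/V")
        lines.append(" " + " ".join(cells[:10]))
        lines.append(" " + " ".join(cells[10:]))
        lines.append("//")
    return "\n".join(lines) + "\n", accessions


def write_aaindex_fixture(path: str | Path, n_indices: int = 20, seed: int = 0,
                          n_na: int = 0) -> list[str]:
    text, accessions = generate_aaindex_fixture(n_indices, seed, n_na)
    Path(path).write_text(text)
    return accessions


# ---------------------------------------------------------------------------
# Hand-checkable micro dataset


@dataclass
class MicroDataset:
    proteins: list[ProteinRecord]
    annotations: list[SiteAnnotation]
    profiles: dict[str, SSProfile]
    positive_windows: list[PeptideWindow]
    negative_windows: list[PeptideWindow]


def worked_micro_dataset() -> MicroDataset:
    """Six 5-residue proteins with four positive lysines, for hand arithmetic.

    Every positive window has 'E' at column 1, so the conservation statistic
    there is exactly (0.95^2 + 19 * 0.05^2) / 0.05 = 19.  Secondary-structure
    profiles are constant per protein: helix-leaning for the positives'
    proteins, coil-leaning for the negatives'.
    """
    pos_seqs = ["AEKLA", "EEKAE", "LEKAA", "AEKEA"]
    neg_seqs = ["LGKGA", "GAKLG"]
    proteins = [
        ProteinRecord(f"micro{i + 1}", s)
        for i, s in enumerate(pos_seqs + neg_seqs)
    ]
    annotations = [
        SiteAnnotation(p.id, 3, 1) for p in proteins[: len(pos_seqs)]
    ]
    profiles = {}
    for i, p in enumerate(proteins):
        row = (0.2, 0.7, 0.1) if i < len(pos_seqs) else (0.7, 0.2, 0.1)
        profiles[p.id] = SSProfile(np.tile(row, (5, 1)), p.sequence)
    pos_windows = [
        PeptideWindow(s, source=(f"micro{i + 1}", 3), label=1)
        for i, s in enumerate(pos_seqs)
    ]
    neg_windows = [
        PeptideWindow(s, source=(f"micro{len(pos_seqs) + j + 1}", 3), label=0)
        for j, s in enumerate(neg_seqs)
    ]
    return MicroDataset(proteins, annotations, profiles, pos_windows, neg_windows)
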