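"""Cis-regulatory sequence features of exon groups.

Covers exon/intron length summaries, the ratio of intron to mean exon
length (RIME, computed on the skipping isoform), maximum-entropy-style
log-odds splice-site scoring, the AG-exclusion zone, and position-wise
motif RNA maps around the four splice-site anchors with a
label-permutation FDR.

Motif matching is on the sense (pre-mRNA) strand with IUPAC codes,
U ≡ T, case-insensitive.  RNA maps use a centred sliding window (27 nt
by default, step 1); a motif counts only when it lies fully inside the
window, and presence/absence per window is recorded (multiple
occurrences in one window count once).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import ExonEvent, SequenceStore
from .stats import bh_fdr

__all__ = [
    "exon_intron_lengths",
    "rime",
    "SpliceSiteModel",
    "train_toy_splice_model",
    "load_splice_model",
    "score_splice_site",
    "relative_score",
    "donor_site_sequence",
    "acceptor_site_sequence",
    "agez",
    "iupac_regex",
    "AnchoredSequence",
    "extract_anchor_sequences",
    "ANCHORS",
    "RnaMapProfile",
    "rna_map",
    "SignificanceTrack",
    "rna_map_significance",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: anchor names in transcript order; donors look exon->intron, acceptors intron->exon
ANCHORS = (
    "upstream_exon_end",
    "alt_exon_start",
    "alt_exon_end",
    "downstream_exon_start",
)
DONOR_ANCHORS = {"upstream_exon_end", "alt_exon_end"}


# ---------------------------------------------------------------------------
# lengths and RIME
# ---------------------------------------------------------------------------

def exon_intron_lengths(events: Iterable[ExonEvent]) -> pd.DataFrame:
    """Per-event alt-exon, flank-exon and intron lengths in nt."""
    rows = []
    for ev in events:
        rows.append(
            {
                "event": ev.event_id,
                "alt_exon": ev.alt_length,
                "upstream_exon": ev.upstream[1] - ev.upstream[0],
                "downstream_exon": ev.downstream[1] - ev.downstream[0],
                "upstream_intron": ev.upstream_intron[1] - ev.upstream_intron[0],
                "downstream_intron": ev.downstream_intron[1] - ev.downstream_intron[0],
            }
        )
    return pd.DataFrame(rows).set_index("event")


def rime(event: ExonEvent) -> float:
    """Ratio of intron to mean exon length for the skipping isoform.

    Total intron = alt exon + upstream intron + downstream intron; mean
    exon = mean of the two flanking constitutive exons.
    """
    up_i = event.upstream_intron[1] - event.upstream_intron[0]
    down_i = event.downstream_intron[1] - event.downstream_intron[0]
    if up_i <= 0 or down_i <= 0:
        raise ValueError(f"zero-length intron in {event.event_id}")
    up_e = event.upstream[1] - event.upstream[0]
    down_e = event.downstream[1] - event.downstream[0]
    if up_e <= 0 or down_e <= 0:
        raise ValueError(f"zero-length flank exon in {event.event_id}")
    return (event.alt_length + up_i + down_i) / ((up_e + down_e) / 2.0)


# ---------------------------------------------------------------------------
# splice-site models
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_BIDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SpliceSiteModel:
    """Log-odds splice-site model: score(seq) = log2 P_fg(seq) / P_bg(seq) in bits.

    ``kind`` is ``donor`` (9-mer: 3 exonic + 6 intronic, Yeo-Burge window
    −3..+6) or ``acceptor`` (23-mer: 20 intronic + 3 exonic, −20..+3).
    Foreground and background are either full k-mer probability tables,
    position-specific (order-0) matrices, or first-order Markov tables.
    """

    kind: str
    length: int
    fg: dict
    bg: dict

    def __post_init__(self) -> None:
        expected = {"donor": 9, "acceptor": 23}
        if self.kind in expected and self.length != expected[self.kind]:
            raise ValueError(f"{self.kind} model must score {expected[self.kind]}-mers")

    def _prob(self, table: dict, seq: str) -> float:
        t = table["type"]
        if t == "kmer":
            try:
                return float(table["table"][seq])
            except KeyError:
                raise ValueError(f"k-mer {seq!r} absent from model table")
        idx = [_BIDX[b] for b in seq]
        if t == "pwm":
            p = table["probs"]
            return float(np.prod([p[i, idx[i]] for i in range(len(idx))]))
        if t == "markov1":
            p = float(table["init"][idx[0]])
            for i in range(1, len(idx)):
                p *= float(table["trans"][i - 1, idx[i - 1], idx[i]])
            return p
        raise ValueError(f"unknown table type {t!r}")

    def score(self, seq: str) -> float:
        seq = seq.upper().replace("U", "T")
        if len(seq) != self.length:
            raise ValueError(f"sequence length {len(seq)} != model length {self.length}")
        if any(b not in _BIDX for b in seq):
            raise ValueError(f"ambiguous base in {seq!r}")
        return float(np.log2(self._prob(self.fg, seq) / self._prob(self.bg, seq)))


def train_toy_splice_model(
    site_seqs: Sequence[str],
    background_seqs: Sequence[str],
    kind: str,
    order: int = 0,
    min_sites: int = 50,
) -> SpliceSiteModel:
    """Train position-specific (order 0) or first-order Markov tables.

    Both foreground and background use add-one smoothing and require
    equal-length training sequences (length must match the site kind).
    """
    def table(seqs: Sequence[str]) -> dict:
        seqs = [s.upper().replace("U", "T") for s in seqs]
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("training sequences differ in length")
        if order == 0:
            counts = np.ones((L, 4))
            for s in seqs:
                for i, b in enumerate(s):
                    counts[i, _BIDX[b]] += 1
            return {"type": "pwm", "probs": counts / counts.sum(axis=1, keepdims=True)}
        if order == 1:
            init = np.ones(4)
            trans = np.ones((L - 1, 4, 4))
            for s in seqs:
                init[_BIDX[s[0]]] += 1
                for i in range(1, L):
                    trans[i - 1, _BIDX[s[i - 1]], _BIDX[s[i]]] += 1
            return {
                "type": "markov1",
                "init": init / init.sum(),
                "trans": trans / trans.sum(axis=2, keepdims=True),
            }
        raise ValueError("order must be 0 or 1")

    if len(site_seqs) < min_sites:
        raise ValueError(f"need at least {min_sites} site sequences")
    L = len(site_seqs[0])
    return SpliceSiteModel(kind, L, table(site_seqs), table(background_seqs))


def load_splice_model(fg_path, bg_path, kind: str) -> SpliceSiteModel:
    """Load full k-mer probability tables (lines: KMER <whitespace> prob)."""
    def read(path) -> dict:
        tab = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                kmer, p = line.split()
                tab[kmer.upper().replace("U", "T")] = float(p)
        if not tab:
            raise ValueError(f"empty model table {path}")
        lengths = {len(k) for k in tab}
        if len(lengths) != 1:
            raise ValueError("heterogeneous k-mer lengths in model table")
        return tab

    fg, bg = read(fg_path), read(bg_path)
    L = len(next(iter(fg)))
    if len(next(iter(bg))) != L:
        raise ValueError("foreground/background k-mer lengths differ")
    return SpliceSiteModel(kind, L, {"type": "kmer", "table": fg},
                           {"type": "kmer", "table": bg})


def score_splice_site(seq: str, model: SpliceSiteModel) -> float:
    return model.score(seq)


def relative_score(scores: Sequence[float], highpsi_scores: Sequence[float]) -> np.ndarray:
    """Centre scores on the median of the constitutive (HighPSI) group."""
    ref = float(np.median(np.asarray(highpsi_scores, dtype=float)))
    return np.asarray(scores, dtype=float) - ref


def _boundary_seq(event: ExonEvent, seqs: SequenceStore, boundary: str,
                  n_exon: int, n_intron: int, donor: bool) -> str:
    """Sense-strand sequence around an exon/intron boundary."""
    plus = event.strand == "+"
    coords = {
        "upstream_exon_end": event.upstream[1] if plus else event.upstream[0],
        "alt_exon_start": event.alt[0] if plus else event.alt[1],
        "alt_exon_end": event.alt[1] if plus else event.alt[0],
        "downstream_exon_start": event.downstream[0] if plus else event.downstream[1],
    }
    g = coords[boundary]
    if donor:
        # exon on the 5' side, intron on the 3' side
        if plus:
            return seqs.fetch(event.chrom, g - n_exon, g + n_intron, "+")
        return seqs.fetch(event.chrom, g - n_intron, g + n_exon, "-")
    if plus:
        return seqs.fetch(event.chrom, g - n_intron, g + n_exon, "+")
    return seqs.fetch(event.chrom, g - n_exon, g + n_intron, "-")


def donor_site_sequence(event: ExonEvent, seqs: SequenceStore,
                        boundary: str = "alt_exon_end") -> str:
    """9-mer donor window (3 exonic + 6 intronic) on the sense strand."""
    if boundary not in DONOR_ANCHORS:
        raise ValueError(f"{boundary!r} is not a donor boundary")
    return _boundary_seq(event, seqs, boundary, 3, 6, donor=True)


def acceptor_site_sequence(event: ExonEvent, seqs: SequenceStore,
                           boundary: str = "alt_exon_start") -> str:
    """23-mer acceptor window (20 intronic + 3 exonic) on the sense strand."""
    if boundary in DONOR_ANCHORS:
        raise ValueError(f"{boundary!r} is not an acceptor boundary")
    return _boundary_seq(event, seqs, boundary, 3, 20, donor=False)


# ---------------------------------------------------------------------------
# AG exclusion zone
# ---------------------------------------------------------------------------

def agez(intron_3p_seq: str, max_scan: int = 250) -> tuple[int, bool]:
    """AG-exclusion zone length of a 3' intron end (sequence ends in AG).

    Scanning upstream from position −3, the AGEZ is the number of nt
    strictly between the intron-terminal AG and the nearest upstream AG
    dinucleotide.  When no upstream AG occurs within ``max_scan`` nt of
    sequence, the available scan length is returned with the capped flag
    set.  Returns ``(length, capped)``.
    """
    s = intron_3p_seq.upper().replace("U", "T")
    if len(s) < 2 or not s.endswith("AG"):
        raise ValueError("3' intron sequence must end in AG")
    # scan upstream: nearest AG dinucleotide fully upstream of the terminal AG
    scan = s[:-2]
    limit = max(len(scan) - (max_scan - 2), 0)
    for i in range(len(scan) - 2, limit - 1, -1):
        if scan[i:i + 2] == "AG":
            return len(scan) - (i + 2), False
    return len(scan) - limit, True


# ---------------------------------------------------------------------------
# RNA maps
# ---------------------------------------------------------------------------

def iupac_regex(motif: str) -> re.Pattern:
    motif = motif.upper().replace("U", "T")
    parts = []
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class AnchoredSequence:
    """A sense-strand sequence with the index of relative position 0.

    Relative position ``p`` maps to sequence index ``anchor + p``; for
    donor anchors position 0 is the first intronic base, for acceptor
    anchors the first exonic base.
    """

    seq: str
    anchor: int


def extract_anchor_sequences(
    events: Iterable[ExonEvent],
    seqs: SequenceStore,
    flank_intron: int = 150,
    flank_exon: int = 35,
) -> dict[str, list[AnchoredSequence]]:
    """Sense-strand sequences around the four splice-site anchors.

    Exonic parts are capped at the exon length and intronic parts at the
    intron length, so windows never cross into neighbouring features;
    truncated positions simply drop out of the profiles.
    """
    out: dict[str, list[AnchoredSequence]] = {a: [] for a in ANCHORS}
    for ev in events:
        up_e = ev.upstream[1] - ev.upstream[0]
        dn_e = ev.downstream[1] - ev.downstream[0]
        alt_e = ev.alt_length
        up_i = ev.upstream_intron[1] - ev.upstream_intron[0]
        dn_i = ev.downstream_intron[1] - ev.downstream_intron[0]
        regions = {
            "upstream_exon_end": (min(flank_exon, up_e), min(flank_intron, up_i), True),
            "alt_exon_start": (min(flank_exon, alt_e), min(flank_intron, up_i), False),
            "alt_exon_end": (min(flank_exon, alt_e), min(flank_intron, dn_i), True),
            "downstream_exon_start": (min(flank_exon, dn_e), min(flank_intron, dn_i), False),
        }
        for name, (n_ex, n_in, donor) in regions.items():
            seq = _boundary_seq(ev, seqs, name, n_ex, n_in, donor=donor)
            anchor = n_ex if donor else n_in
            out[name].append(AnchoredSequence(seq, anchor))
    return out


def default_positions(anchor: str, flank_intron: int = 150, flank_exon: int = 35) -> tuple[int, int]:
    if anchor in DONOR_ANCHORS:
        return (-flank_exon, flank_intron)
    return (-flank_intron, flank_exon)


def _presence_matrix(
    anchored: Sequence[AnchoredSequence],
    motif: str,
    window: int,
    positions: tuple[int, int],
) -> np.ndarray:
    """(n_seq, n_pos) matrix: 1/0 motif presence in the window, NaN undefined.

    A sequence is informative at position p only when the full centred
    window lies inside it; the motif must fall entirely within the window.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    pat = iupac_regex(motif)
    L = len(motif.replace("/", ""))
    lo, hi = positions
    n_pos = hi - lo
    mat = np.full((len(anchored), n_pos), np.nan)
    for r, a in enumerate(anchored):
        s = a.seq.upper().replace("U", "T")
        starts = np.zeros(len(s) + 1, dtype=np.int32)
        for m in pat.finditer(s):
            starts[m.start(1)] = 1
        csum = np.concatenate([[0], np.cumsum(starts[:-1])])
        for p in range(lo, hi):
            w0 = a.anchor + p - half
            w1 = a.anchor + p + half  # inclusive window [w0, w1]
            if w0 < 0 or w1 >= len(s):
                continue
            # match start must be in [w0, w1 - L + 1]
            last = w1 - L + 1
            if last < w0:
                mat[r, p - lo] = 0.0
                continue
            mat[r, p - lo] = 1.0 if csum[last + 1] - csum[w0] > 0 else 0.0
    return mat


@dataclass
class RnaMapProfile:
    """Per-position motif window-coverage for one exon group at one anchor."""

    group: str
    anchor: str
    motif: str
    positions: np.ndarray  # relative positions
    coverage: np.ndarray  # fraction of contributing exons with a match
    n_contrib: np.ndarray  # informative exons per position
    window: int
    min_contrib: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "anchor": self.anchor,
                "position": self.positions,
                "coverage": self.coverage,
                "n": self.n_contrib,
            }
        )


def rna_map(
    anchored: Sequence[AnchoredSequence],
    motif: str,
    window: int = 27,
    positions: tuple[int, int] = (-150, 150),
    group: str = "",
    anchor: str = "",
    min_contrib: int = 1,
) -> RnaMapProfile:
    """Positional motif coverage: fraction of exons with ≥1 full match per window."""
    if not anchored:
        raise ValueError("empty exon group")
    mat = _presence_matrix(anchored, motif, window, positions)
    n = np.sum(np.isfinite(mat), axis=0)
    with np.errstate(invalid="ignore"):
        cov = np.nansum(mat, axis=0) / np.where(n > 0, n, 1)
    cov = np.where(n >= min_contrib, cov, np.nan)
    pos = np.arange(positions[0], positions[1])
    return RnaMapProfile(group, anchor, motif, pos, cov, n, window, min_contrib)


@dataclass
class SignificanceTrack:
    """Permutation-FDR track for a test-vs-control RNA-map contrast."""

    positions: np.ndarray
    statistic: np.ndarray  # coverage(test) - coverage(control)
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_perm: int
    seed: int
    alpha: float = 0.05


def _coverage_diff(mat: np.ndarray, is_test: np.ndarray) -> np.ndarray:
    t = mat[is_test]
    c = mat[~is_test]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(t, axis=0) - np.nanmean(c, axis=0)


def rna_map_significance(
    test: Sequence[AnchoredSequence],
    control: Sequence[AnchoredSequence],
    motif: str,
    window: int = 27,
    positions: tuple[int, int] = (-150, 150),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_contrib: int = 1,
) -> SignificanceTrack:
    """Label-permutation test on the per-position coverage difference.

    The statistic at each position is coverage(test) − coverage(control);
    the null is built by shuffling exon group labels ``n_perm`` times and
    p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), so p ≥ 1/(n_perm+1).
    BH correction runs across defined positions; a position is flagged
    significant when q < alpha.
    """
    if len(test) < 1 or len(control) < 1:
        raise ValueError("both groups must be non-empty")
    if any(t is c for t in test for c in control):
        raise ValueError("test and control groups share exons")
    pooled = list(test) + list(control)
    mat = _presence_matrix(pooled, motif, window, positions)
    n_test = len(test)
    labels = np.zeros(len(pooled), dtype=bool)
    labels[:n_test] = True
    n_t = np.sum(np.isfinite(mat[labels]), axis=0)
    n_c = np.sum(np.isfinite(mat[~labels]), axis=0)
    defined = (n_t >= min_contrib) & (n_c >= min_contrib)
    obs = _coverage_diff(mat, labels)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(mat.shape[1], dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        null = _coverage_diff(mat[perm], labels)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(null) >= abs_obs - 1e-12) & np.isfinite(null) & np.isfinite(abs_obs)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(defined & np.isfinite(obs), p, np.nan)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])
    sig = np.zeros_like(ok)
    sig[ok] = q[ok] < alpha
    pos = np.arange(positions[0], positions[1])
    return SignificanceTrack(pos, obs, p, q, sig, n_perm, seed, alpha)
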