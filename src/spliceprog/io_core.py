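"""Readers, writers and the shared in-memory data model.

All genomic intervals are 0-based half-open internally.  GTF input
(1-based closed) is converted on read.  PSI values are stored in percent
(0-100); a missing measurement is ``NaN`` and is distinct from 0.

Per-cell coverage quality uses the five-level ordinal
``N < VLOW < LOW < OK < SOK``; :func:`read_psi_table` masks cells whose
quality falls below the requested minimum, mirroring the usual practice
of dropping events with very few supporting reads before any ΔPSI
arithmetic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QUALITY_ORDER",
    "PsiMatrix",
    "ExonEvent",
    "GeneAnnotation",
    "Transcript",
    "JunctionCountTable",
    "SequenceStore",
    "ScoreTrack",
    "read_psi_table",
    "write_psi_table",
    "read_junction_counts",
    "read_annotation",
    "read_fasta",
    "read_bedgraph",
    "read_track_and_sequences",
    "events_to_bed",
]

#: coverage-quality ordinal, worst to best
QUALITY_ORDER = ("N", "VLOW", "LOW", "OK", "SOK")
_QRANK = {q: i for i, q in enumerate(QUALITY_ORDER)}

MISSING_TOKENS = {".", "NA", "", "NaN", "nan"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PsiTableError(ValueError):
    """Malformed PSI table (bad value, unknown quality token, ...)."""


# ---------------------------------------------------------------------------
# PSI matrix
# ---------------------------------------------------------------------------

@dataclass
class PsiMatrix:
    """Events x samples PSI percentages with per-cell quality and metadata.

    Parameters
    ----------
    psi
        DataFrame indexed by event id, one column per sample; values in
        [0, 100] or NaN for missing/masked.
    quality
        DataFrame of quality tokens, same shape/labels as ``psi``.
    metadata
        DataFrame indexed by sample id; free-form columns such as
        ``tissue``, ``tissue_group``, ``cell_type``, ``genotype``,
        ``sex``, ``stage``, ``species``, ``dataset``.
    event_info
        Optional per-event columns (GENE, COORD, LENGTH ...).
    """

    psi: pd.DataFrame
    quality: pd.DataFrame
    metadata: pd.DataFrame
    event_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.psi.columns) != list(self.quality.columns) or list(
            self.psi.index
        ) != list(self.quality.index):
            raise PsiTableError("psi and quality must share shape and labels")
        if self.psi.columns.duplicated().any():
            raise PsiTableError("duplicate sample identifiers")
        if self.psi.index.duplicated().any():
            raise PsiTableError("duplicate event identifiers")
        missing_meta = set(self.psi.columns) - set(self.metadata.index)
        if missing_meta:
            raise PsiTableError(f"metadata missing for samples: {sorted(missing_meta)}")
        vals = self.psi.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 100)
        if np.any(bad):
            ev = self.psi.index[np.where(bad)[0][0]]
            sa = self.psi.columns[np.where(bad)[1][0]]
            raise PsiTableError(f"PSI outside [0,100] at event {ev}, sample {sa}")
        qvals = self.quality.to_numpy(dtype=object)
        for tok in np.unique(qvals.astype(str)):
            if tok not in _QRANK:
                raise PsiTableError(f"unknown quality token {tok!r}")

    @property
    def events(self) -> list[str]:
        return list(self.psi.index)

    @property
    def samples(self) -> list[str]:
        return list(self.psi.columns)

    def mask_low_quality(self, min_quality: str) -> "PsiMatrix":
        """Return a copy with cells below ``min_quality`` set to missing."""
        if min_quality not in _QRANK:
            raise PsiTableError(f"unknown quality token {min_quality!r}")
        rank = self.quality.map(lambda q: _QRANK[q])
        masked = self.psi.where(rank >= _QRANK[min_quality])
        return PsiMatrix(masked, self.quality.copy(), self.metadata.copy(),
                         None if self.event_info is None else self.event_info.copy())

    def select_samples(self, samples: Sequence[str]) -> "PsiMatrix":
        samples = list(samples)
        return PsiMatrix(
            self.psi[samples], self.quality[samples],
            self.metadata.loc[samples],
            None if self.event_info is None else self.event_info.copy(),
        )

    def samples_where(self, **criteria: object) -> list[str]:
        """Sample ids whose metadata match all ``column=value`` criteria.

        A value may be a list/tuple/set, meaning membership.
        """
        keep = pd.Series(True, index=self.metadata.index)
        for col, val in criteria.items():
            if col not in self.metadata.columns:
                raise KeyError(f"metadata has no column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                keep &= self.metadata[col].isin(list(val))
            else:
                keep &= self.metadata[col] == val
        return [s for s in self.samples if keep.get(s, False)]


# ---------------------------------------------------------------------------
# annotation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonEvent:
    """A cassette-exon event: alternative exon between two constitutive flanks.

    ``upstream``/``downstream`` are in *transcript* orientation (upstream =
    5' flank).  Intervals are genomic, 0-based half-open.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    alt: tuple[int, int]
    upstream: tuple[int, int]
    downstream: tuple[int, int]
    event_type: str = "cassette"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        a, u, d = self.alt, self.upstream, self.downstream
        for iv in (a, u, d):
            if iv[1] <= iv[0]:
                raise ValueError(f"empty interval {iv} in {self.event_id}")
        if self.strand == "+":
            ok = u[1] <= a[0] <= a[1] <= d[0]
        else:
            ok = d[1] <= a[0] <= a[1] <= u[0]
        if not ok:
            raise ValueError(f"exon order violated in {self.event_id}")

    @property
    def alt_length(self) -> int:
        return self.alt[1] - self.alt[0]

    @property
    def upstream_intron(self) -> tuple[int, int]:
        """Genomic interval between 5' flank and alt exon."""
        if self.strand == "+":
            return (self.upstream[1], self.alt[0])
        return (self.alt[1], self.upstream[0])

    @property
    def downstream_intron(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.alt[1], self.downstream[0])
        return (self.downstream[1], self.alt[0])


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, 0-based half-open
    cds: tuple[int, int] | None = None  # genomic span of the CDS

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    def exons_5to3(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class GeneAnnotation:
    """Genes -> transcripts -> exon structures, plus derived cassette events."""

    transcripts: dict[str, Transcript]
    genes: dict[str, list[str]]  # gene id -> transcript ids

    def cassette_events(self) -> list[ExonEvent]:
        """Derive cassette-exon events by transcript comparison.

        An internal exon of one transcript is a cassette exon when another
        transcript of the same gene joins the two flanking exons directly
        (identical flank coordinates, alt exon absent).  Multiple skipping
        partners are resolved in favour of the longest shared flanks.
        """
        events: dict[tuple, ExonEvent] = {}
        for gene_id, tx_ids in self.genes.items():
            txs = [self.transcripts[t] for t in tx_ids]
            for inc in txs:
                ex = inc.exons  # genomic order
                for i in range(1, len(ex) - 1):
                    up_g, alt, down_g = ex[i - 1], ex[i], ex[i + 1]
                    best = None
                    for skp in txs:
                        if skp is inc:
                            continue
                        sex = skp.exons
                        for j in range(len(sex) - 1):
                            if sex[j] == up_g and sex[j + 1] == down_g:
                                flanklen = (up_g[1] - up_g[0]) + (down_g[1] - down_g[0])
                                if best is None or flanklen > best:
                                    best = flanklen
                    if best is None:
                        continue
                    if inc.strand == "+":
                        up, down = up_g, down_g
                    else:
                        up, down = down_g, up_g
                    key = (gene_id, inc.chrom, inc.strand, alt, up, down)
                    if key not in events:
                        eid = f"{gene_id}:{inc.chrom}:{alt[0]}-{alt[1]}:{inc.strand}"
                        events[key] = ExonEvent(
                            event_id=eid, gene_id=gene_id, chrom=inc.chrom,
                            strand=inc.strand, alt=alt, upstream=up, downstream=down,
                        )
        return list(events.values())


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

@dataclass
class JunctionCountTable:
    """(gene, donor, acceptor) -> junction read count."""

    counts: dict[tuple[str, int, int], int] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, int]]) -> "JunctionCountTable":
        counts: dict[tuple[str, int, int], int] = {}
        for gene, donor, acceptor, n in records:
            key = (gene, int(donor), int(acceptor))
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {key}")
            if key in counts:
                raise ValueError(f"duplicate junction key {key}")
            counts[key] = n
        return cls(counts)

    def get(self, gene: str, donor: int, acceptor: int) -> int:
        return self.counts.get((gene, donor, acceptor), 0)

    def __len__(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# sequences and score tracks
# ---------------------------------------------------------------------------

class SequenceStore:
    """Uppercase nucleotide sequences keyed by contig, with strand-aware fetch."""

    def __init__(self, contigs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in contigs.items()}

    @property
    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"interval [{start},{end}) outside contig {chrom} (len {len(seq)})"
            )
        sub = seq[start:end]
        return sub if strand == "+" else reverse_complement(sub)


class ScoreTrack:
    """Sorted disjoint scored intervals per contig (bedGraph semantics)."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            scores = np.array([i[2] for i in ivs], dtype=float)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if not np.all(np.isfinite(scores)):
                raise ValueError(f"non-finite score on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._scores[chrom] = scores

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base scores over [start,end); NaN where the track is silent."""
        if chrom not in self._starts:
            raise KeyError(f"track has no contig {chrom!r}")
        out = np.full(end - start, np.nan)
        s, e, v = self._starts[chrom], self._ends[chrom], self._scores[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a, b = max(s[i], start), min(e[i], end)
            if a < b:
                out[a - start:b - start] = v[i]
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _format_psi(v: float) -> str:
    if np.isnan(v):
        return "."
    return format(float(v), ".6g")


def read_psi_table(
    path,
    min_quality: str = "LOW",
    metadata: pd.DataFrame | str | None = None,
) -> PsiMatrix:
    """Read a canonical PSI table (EVENT, GENE, COORD, LENGTH, S, S-Q pairs).

    Columns beyond the canonical ones are tolerated when they come in
    SAMPLE / SAMPLE-Q pairs; cells below ``min_quality`` are masked to
    missing.  ``metadata`` may be a DataFrame indexed by sample or a path
    to a TSV with a ``sample`` column; if omitted an empty per-sample
    record is created.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lead = [c for c in ("EVENT", "GENE", "COORD", "LENGTH") if c in df.columns]
    if "EVENT" not in lead:
        raise PsiTableError("PSI table lacks an EVENT column")
    rest = [c for c in df.columns if c not in lead]
    sample_cols = [c for c in rest if not c.endswith("-Q")]
    for c in sample_cols:
        if f"{c}-Q" not in rest:
            raise PsiTableError(f"sample column {c!r} lacks its {c}-Q quality column")

    events = df["EVENT"].tolist()
    psi = pd.DataFrame(index=events, columns=sample_cols, dtype=float)
    qual = pd.DataFrame(index=events, columns=sample_cols, dtype=object)
    for c in sample_cols:
        vals = []
        for row, tok in zip(events, df[c]):
            if tok in MISSING_TOKENS:
                vals.append(np.nan)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise PsiTableError(f"non-numeric PSI {tok!r} at event {row}, sample {c}")
            if not 0.0 <= v <= 100.0:
                raise PsiTableError(f"PSI {v} outside [0,100] at event {row}, sample {c}")
            vals.append(v)
        psi[c] = vals
        for row, tok in zip(events, df[f"{c}-Q"]):
            if tok not in _QRANK:
                raise PsiTableError(f"unknown quality token {tok!r} at event {row}, sample {c}")
        qual[c] = list(df[f"{c}-Q"])

    if metadata is None:
        meta = pd.DataFrame(index=sample_cols)
    elif isinstance(metadata, pd.DataFrame):
        meta = metadata
    else:
        meta = pd.read_csv(metadata, sep="\t", dtype=str).set_index("sample")

    info_cols = [c for c in lead if c != "EVENT"]
    event_info = df[info_cols].set_axis(events) if info_cols else None
    mat = PsiMatrix(psi, qual, meta, event_info)
    if min_quality is not None:
        mat = mat.mask_low_quality(min_quality)
    return mat


def write_psi_table(matrix: PsiMatrix, path) -> None:
    """Write the canonical PSI-table dialect (inverse of :func:`read_psi_table`)."""
    cols = ["EVENT"]
    if matrix.event_info is not None:
        cols += list(matrix.event_info.columns)
    out = io.StringIO()
    header = cols[:]
    for s in matrix.samples:
        header += [s, f"{s}-Q"]
    out.write("\t".join(header) + "\n")
    for ev in matrix.events:
        row = [str(ev)]
        if matrix.event_info is not None:
            row += [str(x) for x in matrix.event_info.loc[ev]]
        for s in matrix.samples:
            row.append(_format_psi(matrix.psi.at[ev, s]))
            row.append(str(matrix.quality.at[ev, s]))
        out.write("\t".join(row) + "\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(out.getvalue())


def read_junction_counts(path) -> JunctionCountTable:
    """Read a TSV with columns gene, donor, acceptor, count."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "donor", "acceptor", "count"}
    if not need.issubset(df.columns):
        raise ValueError(f"junction table must have columns {sorted(need)}")
    return JunctionCountTable.from_records(
        df[["gene", "donor", "acceptor", "count"]].itertuples(index=False, name=None)
    )


def read_annotation(gtf_path) -> GeneAnnotation:
    """Parse a GTF into a :class:`GeneAnnotation` (coordinates to 0-based)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, Transcript] = {}
    genes: dict[str, list[str]] = {}
    for tx in db.features_of_type("transcript"):
        if tx.strand not in "+-":
            raise ValueError(f"unknown strand {tx.strand!r} on {tx.id}")
        exons = []
        cds_lo, cds_hi = None, None
        for child in db.children(tx, featuretype="exon"):
            s, e = child.start - 1, child.end  # GTF 1-based closed -> half-open
            if s < tx.start - 1 or e > tx.end:
                raise ValueError(f"exon outside transcript bounds in {tx.id}")
            exons.append((s, e))
        for child in db.children(tx, featuretype="CDS"):
            s, e = child.start - 1, child.end
            cds_lo = s if cds_lo is None else min(cds_lo, s)
            cds_hi = e if cds_hi is None else max(cds_hi, e)
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        cds = None if cds_lo is None else (cds_lo, cds_hi)
        transcripts[tx.id] = Transcript(tx.id, gene_id, tx.seqid, tx.strand, exons, cds)
        genes.setdefault(gene_id, []).append(tx.id)
    return GeneAnnotation(transcripts, genes)


def read_fasta(path) -> SequenceStore:
    from Bio import SeqIO

    return SequenceStore({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def read_bedgraph(path) -> ScoreTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, score = line.split("\t")[:4]
            intervals.setdefault(chrom, []).append((int(start), int(end), float(score)))
    return ScoreTrack(intervals)


def read_track_and_sequences(fasta_path, bedgraph_path) -> tuple[SequenceStore, ScoreTrack]:
    """Load a FASTA and a bedGraph on the same assembly, cross-checking contigs.

    Track intervals extending past the contig end are clipped with a warning;
    a bedGraph contig absent from the FASTA is an error.
    """
    seqs = read_fasta(fasta_path)
    track = read_bedgraph(bedgraph_path)
    lengths = seqs.contigs
    clipped: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in track.chroms:
        if chrom not in lengths:
            raise ValueError(f"bedGraph contig {chrom!r} absent from FASTA")
        L = lengths[chrom]
        ivs = []
        for s, e, v in zip(track._starts[chrom], track._ends[chrom], track._scores[chrom]):
            if e > L:
                warnings.warn(f"clipping track interval [{s},{e}) to contig {chrom} length {L}")
                e = L
            if s < e:
                ivs.append((int(s), int(e), float(v)))
        clipped[chrom] = ivs
    return seqs, ScoreTrack(clipped)


def events_to_bed(events: Iterable[ExonEvent], path) -> None:
    """Export alt-exon coordinates as BED6."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.chrom}\t{ev.alt[0]}\t{ev.alt[1]}\t{ev.event_id}\t0\t{ev.strand}\n"
            )
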