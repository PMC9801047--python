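"""Alternative splicing events: detection from a gene model and PSI quantification.

Five canonical event types are recognised from annotated transcript
structures by pairwise comparison of exon chains within a gene:

* **SE** -- skipped (cassette) exon: an internal exon present in one
  transcript whose flanking exons are spliced directly together in another.
* **MXE** -- mutually exclusive exons: two non-overlapping internal exons
  that share both flanking junctions but never co-occur.
* **A5SS / A3SS** -- alternative 5'/3' splice site: two transcripts share
  one junction boundary but use different donor (5') or acceptor (3')
  sites; the labels are mirrored on the minus strand.
* **RI** -- retained intron: an exon pair in one transcript whose merged
  span is a single exon in another.

Percent spliced-in is the length-normalised inclusion fraction

    psi = (I / l_I) / (I / l_I + E / l_S)

where ``I`` and ``E`` are inclusion / exclusion read counts and ``l_I``,
``l_S`` are effective lengths.  In junction-count mode the effective
lengths are simply the number of junctions supporting each isoform
(SE 2/1, MXE 2/2, A5SS 1/1, A3SS 1/1, RI 1/1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("A5SS", "A3SS", "SE", "MXE", "RI")

#: junctions supporting the inclusion / exclusion isoform, per event type
_JUNCTION_COUNTS: dict[str, tuple[int, int]] = {
    "SE": (2, 1),
    "MXE": (2, 2),
    "A5SS": (1, 1),
    "A3SS": (1, 1),
    "RI": (1, 1),
}


@dataclass(frozen=True)
class Transcript:
    """An exon chain. Coordinates are 1-based inclusive, GTF dialect."""

    tx_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def junctions(self) -> set[tuple[int, int]]:
        """Set of (donor_end, acceptor_start) pairs in genomic order."""
        return {
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        }

    def exon_set(self) -> set[tuple[int, int]]:
        return set(self.exons)


@dataclass
class GeneModel:
    """Mapping of gene -> transcripts, with malformed transcripts rejected."""

    genes: dict[str, list[Transcript]] = field(default_factory=dict)

    def add_transcript(self, gene_id: str, tx: Transcript) -> bool:
        """Add ``tx`` under ``gene_id``; returns False (and logs) if malformed.

        A transcript is malformed if its exons are unsorted or overlap.
        """
        if not tx.exons:
            logger.warning("transcript %s has no exons; skipped", tx.tx_id)
            return False
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            if not (s1 <= e1 and e1 < s2 and s2 <= e2):
                logger.warning(
                    "transcript %s has malformed exon ordering; skipped", tx.tx_id
                )
                return False
        if tx.exons[0][0] > tx.exons[0][1]:
            logger.warning("transcript %s has inverted exon; skipped", tx.tx_id)
            return False
        self.genes.setdefault(gene_id, []).append(tx)
        return True

    @classmethod
    def from_gtf(cls, path: str) -> "GeneModel":
        """Build a gene model from a GTF file (requires gene_id/transcript_id)."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="merge",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        chains: dict[tuple[str, str], list[tuple[str, str, int, int]]] = {}
        for exon in db.features_of_type("exon"):
            gene_id = exon.attributes["gene_id"][0]
            tx_id = exon.attributes["transcript_id"][0]
            chains.setdefault((gene_id, tx_id), []).append(
                (exon.seqid, exon.strand, exon.start, exon.end)
            )
        model = cls()
        for (gene_id, tx_id), rows in sorted(chains.items()):
            rows.sort(key=lambda r: (r[2], r[3]))
            chrom, strand = rows[0][0], rows[0][1]
            tx = Transcript(
                tx_id=tx_id,
                chrom=chrom,
                strand=strand,
                exons=tuple((s, e) for _, _, s, e in rows),
            )
            model.add_transcript(gene_id, tx)
        return model


@dataclass(frozen=True, order=True)
class ASEvent:
    """One annotated splicing event with a canonical coordinate tuple.

    ``coords`` is strictly increasing in genomic order; its arity depends
    on the type (SE/RI/A5SS/A3SS: 4, MXE: 6).  ``event_id`` is a pure
    function of (type, gene, chrom, strand, coords).
    """

    type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown AS event type: {self.type}")
        if list(self.coords) != sorted(self.coords) or len(set(self.coords)) != len(
            self.coords
        ):
            raise ValueError(f"coordinates not strictly increasing: {self.coords}")

    @property
    def event_id(self) -> str:
        pairs = ":".join(
            f"{self.coords[i]}-{self.coords[i + 1]}"
            for i in range(0, len(self.coords), 2)
        )
        return f"{self.type}:{self.gene_id}:{self.chrom}:{self.strand}:{pairs}"


def _pair_events(
    gene_id: str, ta: Transcript, tb: Transcript
) -> Iterable[ASEvent]:
    """Enumerate events witnessed by the ordered transcript pair (ta, tb).

    ``ta`` supplies the inclusion form; structural differences are
    classified by pattern-matching the two exon chains.
    """
    chrom, strand = ta.chrom, ta.strand
    jb = tb.junctions()
    xb = tb.exon_set()
    xa = ta.exon_set()

    exons = ta.exons
    # SE: internal exon of ta skipped by a direct flank junction in tb
    for i in range(1, len(exons) - 1):
        up, ex, dn = exons[i - 1], exons[i], exons[i + 1]
        if (up[1], dn[0]) in jb and ex not in xb:
            yield ASEvent("SE", gene_id, chrom, strand, (up[1], ex[0], ex[1], dn[0]))

    # RI: adjacent exon pair in ta merged into one exon in tb
    for e1, e2 in zip(exons, exons[1:]):
        if (e1[0], e2[1]) in xb:
            yield ASEvent("RI", gene_id, chrom, strand, (e1[0], e1[1], e2[0], e2[1]))

    # alternative donor / acceptor: junction pairs sharing one boundary
    for i in range(len(exons) - 1):
        u1, v1 = exons[i], exons[i + 1]
        for j in range(len(tb.exons) - 1):
            u2, v2 = tb.exons[j], tb.exons[j + 1]
            # shared acceptor, different donors, same upstream exon start
            if v1[0] == v2[0] and u1[1] != u2[1] and u1[0] == u2[0]:
                lo, hi = sorted((u1[1], u2[1]))
                if u1[0] < lo and hi < v1[0]:
                    kind = "A5SS" if strand == "+" else "A3SS"
                    yield ASEvent(kind, gene_id, chrom, strand, (u1[0], lo, hi, v1[0]))
            # shared donor, different acceptors, same downstream exon end
            if u1[1] == u2[1] and v1[0] != v2[0] and v1[1] == v2[1]:
                lo, hi = sorted((v1[0], v2[0]))
                if u1[1] < lo and hi < v1[1]:
                    kind = "A3SS" if strand == "+" else "A5SS"
                    yield ASEvent(kind, gene_id, chrom, strand, (u1[1], lo, hi, v1[1]))

    # MXE: internal exons sharing both flank junctions, mutually absent
    for i in range(1, len(exons) - 1):
        up, x, dn = exons[i - 1], exons[i], exons[i + 1]
        for j in range(1, len(tb.exons) - 1):
            up2, y, dn2 = tb.exons[j - 1], tb.exons[j], tb.exons[j + 1]
            if up[1] != up2[1] or dn[0] != dn2[0] or x == y:
                continue
            if x in xb or y in xa:
                continue
            if x[1] < y[0] or y[1] < x[0]:  # non-overlapping
                first, second = sorted((x, y))
                coords = (up[1], first[0], first[1], second[0], second[1], dn[0])
                if list(coords) == sorted(set(coords)):
                    yield ASEvent("MXE", gene_id, chrom, strand, coords)


def detect_events(model: GeneModel) -> list[ASEvent]:
    """Enumerate AS events by pairwise transcript comparison within each gene.

    Deduplicated by canonical coordinate tuple; genes with a single
    transcript yield no events.  The result is independent of transcript
    input order.
    """
    if not model.genes:
        raise ValueError("gene model is empty")
    found: set[ASEvent] = set()
    for gene_id, txs in model.genes.items():
        if len(txs) < 2:
            continue
        for a in range(len(txs)):
            for b in range(len(txs)):
                if a == b:
                    continue
                found.update(_pair_events(gene_id, txs[a], txs[b]))
    return sorted(found)


@dataclass(frozen=True)
class EffectiveLengths:
    lI: float
    lS: float


def effective_lengths(
    event_type: str,
    read_length: int | None = None,
    anchor: int = 8,
    junction_count: bool = True,
) -> EffectiveLengths:
    """Effective lengths of the inclusion / exclusion isoforms.

    In junction-count mode (default) the lengths equal the number of
    junctions supporting each form.  In length-weighted mode each junction
    contributes ``read_length - 2 * anchor + 1`` mappable positions, which
    requires ``read_length > 2 * anchor``.
    """
    if event_type not in _JUNCTION_COUNTS:
        raise ValueError(f"unknown AS event type: {event_type}")
    n_inc, n_exc = _JUNCTION_COUNTS[event_type]
    if junction_count:
        return EffectiveLengths(float(n_inc), float(n_exc))
    if read_length is None:
        raise ValueError("read_length required in length-weighted mode")
    if read_length <= 2 * anchor:
        raise ValueError("read_length must exceed 2 * anchor")
    span = read_length - 2 * anchor + 1
    return EffectiveLengths(float(n_inc * span), float(n_exc * span))


def compute_psi(I, E, lI: float = 1.0, lS: float = 1.0):
    """psi = (I/lI) / (I/lI + E/lS); NaN (missing) where I + E == 0.

    Accepts scalars or arrays; scale-invariant in (I, E) jointly,
    monotone non-decreasing in I and non-increasing in E.
    """
    I = np.asarray(I, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(I < 0) or np.any(E < 0):
        raise ValueError("read counts must be non-negative")
    if lI <= 0 or lS <= 0:
        raise ValueError("effective lengths must be positive")
    inc = I / lI
    exc = E / lS
    denom = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, inc / np.where(denom > 0, denom, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi) if denom > 0 else float("nan")
    return psi


def psi_from_junction_counts(
    counts: pd.DataFrame, event_types: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Pivot a long junction-count table into an events x samples PSI matrix.

    ``counts`` columns: event_id, sample_id, I, E.  If ``event_types`` maps
    event_id -> type, junction-count effective lengths are applied;
    otherwise the type is taken from the event_id prefix.
    """
    required = {"event_id", "sample_id", "I", "E"}
    if not required.issubset(counts.columns):
        raise ValueError(f"junction-count table needs columns {sorted(required)}")

    def _etype(eid: str) -> str:
        if event_types is not None:
            return event_types[eid]
        return str(eid).split(":", 1)[0]

    psi_vals = np.empty(len(counts))
    for pos, (eid, i_val, e_val) in enumerate(
        zip(counts["event_id"], counts["I"], counts["E"])
    ):
        el = effective_lengths(_etype(eid))
        psi_vals[pos] = compute_psi(i_val, e_val, el.lI, el.lS)
    long = counts[["event_id", "sample_id"]].copy()
    long["psi"] = psi_vals
    return long.pivot(index="event_id", columns="sample_id", values="psi")


def filter_events(
    psi: pd.DataFrame,
    low_var: float | None = None,
    prop_na: float = 0.05,
    prop_extreme: float = 1.0,
) -> pd.DataFrame:
    """Drop events with too many missing or extreme (exactly 0/1) PSI values.

    An event is removed when its missing proportion exceeds ``prop_na``,
    when its proportion of values exactly 0 or 1 exceeds ``prop_extreme``,
    or (if ``low_var`` is set) when its variance over non-missing values
    falls below ``low_var``.
    """
    if psi.empty:
        raise ValueError("PSI matrix is empty")
    n = psi.shape[1]
    vals = psi.to_numpy(dtype=float)
    na_prop = np.isnan(vals).sum(axis=1) / n
    keep = na_prop <= prop_na
    with np.errstate(invalid="ignore"):
        extreme = np.nansum((vals == 0.0) | (vals == 1.0), axis=1) / n
    keep &= extreme <= prop_extreme
    if low_var is not None:
        with np.errstate(invalid="ignore"):
            variance = np.nanvar(vals, axis=1, ddof=1)
        keep &= np.nan_to_num(variance) >= low_var
    out = psi.loc[keep]
    if out.empty:
        logger.warning("all events removed by PSI filtering")
    return out


def events_to_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    """Serialize events to the TSV-ready table layout."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "type": [e.type for e in events],
            "gene_id": [e.gene_id for e in events],
            "chrom": [e.chrom for e in events],
            "strand": [e.strand for e in events],
            "coords": [",".join(map(str, e.coords)) for e in events],
        }
    )


def events_from_table(table: pd.DataFrame) -> list[ASEvent]:
    return [
        ASEvent(
            type=row.type,
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            coords=tuple(int(c) for c in str(row.coords).split(",")),
        )
        for row in table.itertuples()
    ]
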