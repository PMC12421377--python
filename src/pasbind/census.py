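"""Census of annotated polyadenylation signals in genome annotation.

Reads GFF3 (+ genome FASTA) or GenBank flat files, extracts every annotated
poly(A)-signal feature as an RNA hexamer on its transcript, and tabulates
hexamer frequencies stratified by where each signal sits among its
transcript's signals (single / first / intermediate / last).  Counting is per
feature-transcript association by default — a signal shared by several
isoforms counts once per transcript — with genomic deduplication available
as an option.

Recognized annotation dialects (RefSeq conventions have drifted over time):

* GFF3 feature types ``regulatory_region`` / ``region`` carrying a
  ``regulatory_class=polyA_signal_sequence`` attribute;
* GFF3 feature type ``polyA_signal_sequence``;
* the legacy GFF3/GenBank key ``polyA_signal``;
* GenBank ``regulatory`` features with a ``regulatory_class`` qualifier.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from gffutils.iterators import DataIterator
from pyfaidx import Fasta

from .hexamers import RNA_ALPHABET

__all__ = [
    "PasFeature",
    "FrequencyTable",
    "ParseResult",
    "parse_annotation",
    "parse_gff3",
    "parse_genbank",
    "census",
    "skip_report",
    "census_to_frame",
]

STRATA = ("all", "single", "first", "intermediate", "last")

_GFF_REGULATORY_TYPES = {"regulatory_region", "region"}
_GFF_DIRECT_TYPES = {"polyA_signal_sequence", "polyA_signal"}
_PAS_CLASS = "polyA_signal_sequence"


@dataclass
class PasFeature:
    """One annotated poly(A) signal on one transcript (1-based inclusive)."""

    transcript_id: str
    hexamer: str
    chrom: str
    start: int
    end: int
    strand: str
    ordinal: int = 0  # 1-based index in transcript 5'->3' order
    n_on_transcript: int = 0


@dataclass
class ParseResult:
    """Extracted features plus an accounting of everything excluded."""

    features: list[PasFeature]
    skipped: Counter = field(default_factory=Counter)
    n_orphans: int = 0  # kept, but assigned to synthetic singleton transcripts


@dataclass
class FrequencyTable:
    """Hexamer counts and percentages for one positional stratum."""

    stratum: str
    counts: dict[str, int]
    total: int

    @property
    def percent(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {h: 100.0 * c / self.total for h, c in self.counts.items()}


def _dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _assign_ordinals(features: list[PasFeature]) -> list[PasFeature]:
    """Order each transcript's signals 5'->3' (genomic ascending on +,
    descending on -) and fill ordinal / n_on_transcript."""
    by_tx: dict[str, list[PasFeature]] = defaultdict(list)
    for f in features:
        by_tx[f.transcript_id].append(f)
    for tx_feats in by_tx.values():
        minus = tx_feats[0].strand == "-"
        tx_feats.sort(key=lambda f: f.start, reverse=minus)
        for i, f in enumerate(tx_feats, start=1):
            f.ordinal = i
            f.n_on_transcript = len(tx_feats)
    return features


def _admit(result: ParseResult, feat: PasFeature) -> None:
    """Validate hexamer length/alphabet; append or record the exclusion."""
    if len(feat.hexamer) != 6:
        result.skipped["length_mismatch"] += 1
        return
    if not set(feat.hexamer) <= RNA_ALPHABET:
        result.skipped["alphabet"] += 1
        return
    result.features.append(feat)


def parse_gff3(gff_path, fasta_path) -> ParseResult:
    """Extract poly(A)-signal features from GFF3 + genome FASTA.

    Transcript association uses the Parent attribute, falling back to
    containment within an mRNA interval on the same contig and strand;
    features with neither are kept on a synthetic singleton transcript.
    """
    result = ParseResult(features=[])
    mrnas: dict[str, tuple[str, int, int, str]] = {}
    candidates = []
    for feat in DataIterator(str(gff_path)):
        ftype = feat.featuretype
        if ftype == "mRNA":
            fid = feat.attributes.get("ID", [None])[0]
            if fid:
                mrnas[fid] = (feat.seqid, feat.start, feat.end, feat.strand)
            continue
        is_pas = ftype in _GFF_DIRECT_TYPES or (
            ftype in _GFF_REGULATORY_TYPES
            and _PAS_CLASS in feat.attributes.get("regulatory_class", [])
        )
        if is_pas:
            candidates.append(feat)

    genome = Fasta(str(fasta_path), as_raw=True, rebuild=False)
    by_contig: dict[str, list[tuple[str, int, int, str]]] = defaultdict(list)
    for fid, (chrom, s, e, st) in mrnas.items():
        by_contig[chrom].append((fid, s, e, st))

    for feat in candidates:
        parents = feat.attributes.get("Parent", [])
        tx_ids = [p for p in parents if p in mrnas]
        if not tx_ids and parents:
            tx_ids = parents  # Parent given but unknown: keep the stated id
        if not tx_ids:
            tx_ids = [
                fid for fid, s, e, st in by_contig.get(feat.seqid, [])
                if s <= feat.start and feat.end <= e and st == feat.strand
            ]
        if not tx_ids:
            tx_ids = [f"orphan:{feat.seqid}:{feat.start}-{feat.end}({feat.strand})"]
            result.n_orphans += 1
        seq = str(genome[feat.seqid][feat.start - 1:feat.end])
        if feat.strand == "-":
            seq = _revcomp(seq)
        hexamer = _dna_to_rna(seq)
        for tx in tx_ids:
            _admit(result, PasFeature(
                transcript_id=tx, hexamer=hexamer, chrom=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand,
            ))
    _assign_ordinals(result.features)
    return result


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def parse_genbank(gb_path) -> ParseResult:
    """Extract poly(A)-signal features from a GenBank flat file.

    Transcript association matches the feature's locus_tag/gene qualifier
    against the record's mRNA features, then containment, then a synthetic
    singleton transcript.
    """
    result = ParseResult(features=[])
    for record in SeqIO.parse(str(gb_path), "genbank"):
        mrnas = []
        candidates = []
        for feat in record.features:
            if feat.type == "mRNA":
                mrnas.append(feat)
            elif feat.type == "regulatory":
                if _PAS_CLASS in feat.qualifiers.get("regulatory_class", []):
                    candidates.append(feat)
            elif feat.type == "polyA_signal":
                candidates.append(feat)
        mrna_by_tag: dict[str, object] = {}
        for m in mrnas:
            for key in ("locus_tag", "gene"):
                for tag in m.qualifiers.get(key, []):
                    mrna_by_tag.setdefault(tag, m)
        for feat in candidates:
            tags = feat.qualifiers.get("locus_tag", []) or feat.qualifiers.get("gene", [])
            tx_ids = [t for t in tags if t in mrna_by_tag] or list(tags)
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            if not tx_ids:
                tx_ids = [
                    next(iter(m.qualifiers.get("locus_tag", m.qualifiers.get("gene", ["?"]))))
                    for m in mrnas
                    if int(m.location.start) < start and end <= int(m.location.end)
                    and ("-" if m.location.strand == -1 else "+") == strand
                ]
            if not tx_ids:
                tx_ids = [f"orphan:{record.id}:{start}-{end}({strand})"]
                result.n_orphans += 1
            hexamer = _dna_to_rna(str(feat.extract(record.seq)))
            for tx in tx_ids:
                _admit(result, PasFeature(
                    transcript_id=tx, hexamer=hexamer, chrom=record.id,
                    start=start, end=end, strand=strand,
                ))
    _assign_ordinals(result.features)
    return result


def parse_annotation(annotation, fasta=None) -> ParseResult:
    """Dispatch on annotation format: GFF3 (requires ``fasta``) or GenBank."""
    path = Path(annotation)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        if fasta is None:
            raise ValueError("GFF3 annotation requires a genome FASTA")
        return parse_gff3(path, fasta)
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return parse_genbank(path)
    # sniff: GenBank flat files start with LOCUS
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        return parse_genbank(path)
    if fasta is None:
        raise ValueError(f"cannot identify format of {path} (GFF3 needs a FASTA)")
    return parse_gff3(path, fasta)


def census(features: list[PasFeature], dedupe_genomic: bool = False) -> dict[str, FrequencyTable]:
    """Stratified hexamer frequency tables.

    Strata: ``all`` (every signal), ``single`` (transcripts with one signal),
    ``first`` / ``last`` (ends of multi-signal transcripts), ``intermediate``
    (interior signals of transcripts with >= 3).  With ``dedupe_genomic``,
    signals sharing a genomic interval count once (the 'all' stratum only;
    positional strata are transcript-relative and keep per-transcript counts).
    """
    tables: dict[str, FrequencyTable] = {}
    selectors = {
        "all": lambda f: True,
        "single": lambda f: f.n_on_transcript == 1,
        "first": lambda f: f.ordinal == 1 and f.n_on_transcript >= 2,
        "last": lambda f: f.ordinal == f.n_on_transcript and f.n_on_transcript >= 2,
        "intermediate": lambda f: 1 < f.ordinal < f.n_on_transcript,
    }
    for stratum in STRATA:
        sel = [f for f in features if selectors[stratum](f)]
        if stratum == "all" and dedupe_genomic:
            seen = set()
            uniq = []
            for f in sel:
                key = (f.chrom, f.start, f.end, f.strand)
                if key not in seen:
                    seen.add(key)
                    uniq.append(f)
            sel = uniq
        counts = Counter(f.hexamer for f in sel)
        tables[stratum] = FrequencyTable(
            stratum=stratum, counts=dict(counts), total=sum(counts.values())
        )
    return tables


def skip_report(result: ParseResult) -> dict[str, int]:
    """Counts of excluded features by reason, plus orphan associations kept."""
    return {
        "length_mismatch": result.skipped.get("length_mismatch", 0),
        "alphabet": result.skipped.get("alphabet", 0),
        "orphan": result.n_orphans,
        "counted": len(result.features),
    }


def census_to_frame(tables: dict[str, FrequencyTable]) -> pd.DataFrame:
    """Long-format table: stratum, hexamer, count, percent (sorted)."""
    rows = []
    for stratum in STRATA:
        t = tables[stratum]
        pct = t.percent
        for h in sorted(t.counts):
            rows.append({"stratum": stratum, "hexamer": h,
                         "count": t.counts[h], "percent": pct[h]})
    return pd.DataFrame(rows, columns=["stratum", "hexamer", "count", "percent"])
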