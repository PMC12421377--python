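"""Synthetic data generators: simulated anisotropy titrations and annotated
genome corpora with planted polyadenylation signals.

Both generators are pure functions of their specification plus a seed, and
every corpus is emitted together with its ground-truth table so downstream
recovery can be checked against what was actually planted rather than
against hard-coded numbers.

Default assay designs mirror the study conditions the package targets:
3 nM labeled probe with the receptor serially diluted from 300 nM down to
0.04 nM (direct assays), and 3 nM probe / 30 nM receptor with the unlabeled
competitor diluted from 100 uM down to 0.5 nM (competition assays), both in
triplicate.  Dilutions are two-fold by default; the additive anisotropy
noise is i.i.d. Gaussian with sigma = 0.005, a typical plate-reader scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .equilibrium import fraction_bound_direct, free_receptor_competitive
from .fitting import TitrationCurve, TitrationPoint, predict_anisotropy
from .hexamers import RNA_ALPHABET, load_reference_table

__all__ = [
    "AssayDesign",
    "CorpusSpec",
    "CorpusFiles",
    "serial_dilution",
    "direct_design",
    "competition_design",
    "simulate_direct_curve",
    "simulate_competition_curve",
    "generate_corpus",
    "reference_hexamer_distribution",
]

DEFAULT_NOISE_SD = 0.005  # anisotropy units; not taken from any measured assay


def serial_dilution(titrant_max: float, dilution_factor: float, n_points: int) -> np.ndarray:
    """Geometric dilution series: max, max/f, ..., length ``n_points``."""
    if not dilution_factor > 1:
        raise ValueError("dilution_factor must be > 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    return titrant_max / dilution_factor ** np.arange(n_points)


@dataclass(frozen=True)
class AssayDesign:
    """Concentration layout and noise model of one titration experiment."""

    probe_total: float  # nM
    titrant_max: float  # nM
    titrant_min: float  # nM
    receptor_total: float | None = None  # nM; competition assays only
    dilution_factor: float = 2.0
    n_replicates: int = 3
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.titrant_max > self.titrant_min > 0):
            raise ValueError("need titrant_max > titrant_min > 0")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must be > 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def concentrations(self) -> np.ndarray:
        """Serial dilution from titrant_max downward while >= titrant_min."""
        n = math.floor(math.log(self.titrant_max / self.titrant_min, self.dilution_factor)) + 1
        series = serial_dilution(self.titrant_max, self.dilution_factor, n)
        return series[series >= self.titrant_min * (1 - 1e-12)]


def direct_design(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD, n_replicates: int = 3) -> AssayDesign:
    """Direct-assay layout: 3 nM probe, receptor 300 -> 0.04 nM, 2-fold steps."""
    return AssayDesign(probe_total=3.0, titrant_max=300.0, titrant_min=0.04,
                       noise_sd=noise_sd, n_replicates=n_replicates, seed=seed)


def competition_design(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD, n_replicates: int = 3) -> AssayDesign:
    """Competition layout: 3 nM probe, 30 nM receptor, competitor 100 uM -> 0.5 nM."""
    return AssayDesign(probe_total=3.0, receptor_total=30.0, titrant_max=1e5,
                       titrant_min=0.5, noise_sd=noise_sd,
                       n_replicates=n_replicates, seed=seed)


def _noisy_points(design: AssayDesign, concs: np.ndarray, ideal: np.ndarray) -> list[TitrationPoint]:
    rng = np.random.default_rng(design.seed)
    points = []
    for rep in range(1, design.n_replicates + 1):
        noise = rng.normal(0.0, design.noise_sd, size=ideal.size) if design.noise_sd > 0 else 0.0
        readings = ideal + noise
        points.extend(
            TitrationPoint(float(c), float(a), rep) for c, a in zip(concs, np.atleast_1d(readings))
        )
    return points


def simulate_direct_curve(design: AssayDesign, kd_true: float,
                          r_free: float = 0.05, r_bound: float = 0.20) -> TitrationCurve:
    """Simulate a direct receptor titration of a labeled probe."""
    concs = design.concentrations
    fb = fraction_bound_direct(concs, design.probe_total, kd_true)
    ideal = predict_anisotropy(fb, r_free, r_bound)
    return TitrationCurve(
        assay_kind="direct", probe_total=design.probe_total,
        points=_noisy_points(design, concs, ideal),
        meta={"kd_true_nM": kd_true, "r_free_true": r_free, "r_bound_true": r_bound,
              "noise_sd": design.noise_sd, "seed": design.seed},
    )


def simulate_competition_curve(design: AssayDesign, kd_probe: float, kd_competitor_true: float,
                               r_free: float = 0.05, r_bound: float = 0.20) -> TitrationCurve:
    """Simulate a competition titration: unlabeled competitor displaces the probe."""
    if design.receptor_total is None:
        raise ValueError("competition design requires receptor_total")
    concs = design.concentrations
    r = free_receptor_competitive(design.receptor_total, design.probe_total,
                                  concs, kd_probe, kd_competitor_true)
    fb = r / (kd_probe + r)
    ideal = predict_anisotropy(fb, r_free, r_bound)
    return TitrationCurve(
        assay_kind="competition", probe_total=design.probe_total,
        receptor_total=design.receptor_total, kd_probe=kd_probe,
        points=_noisy_points(design, concs, ideal),
        meta={"kd_competitor_true_nM": kd_competitor_true, "noise_sd": design.noise_sd,
              "seed": design.seed},
    )


# ---------------------------------------------------------------------------
# synthetic annotation corpus
# ---------------------------------------------------------------------------

_DEFAULT_PAS_COUNTS = {1: 0.55, 2: 0.25, 3: 0.13, 4: 0.07}


def reference_hexamer_distribution() -> dict[str, float]:
    """Packaged-panel annotation frequencies renormalized to sum to 1."""
    df = load_reference_table()
    df = df[df["label"] != "FAM"]
    total = df["frequency_percent"].sum()
    return {h: f / total for h, f in zip(df["hexamer"], df["frequency_percent"])}


@dataclass(frozen=True)
class CorpusSpec:
    """Layout of a synthetic annotated genome with planted poly(A) signals."""

    n_transcripts: int
    hexamer_distribution: dict[str, float] = None
    pas_count_distribution: dict[int, float] = None
    strand_fraction_minus: float = 0.5
    intergenic_pad: int = 50
    transcripts_per_contig: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hexamer_distribution is None:
            object.__setattr__(self, "hexamer_distribution", reference_hexamer_distribution())
        if self.pas_count_distribution is None:
            object.__setattr__(self, "pas_count_distribution", dict(_DEFAULT_PAS_COUNTS))
        for dist, name in ((self.hexamer_distribution, "hexamer_distribution"),
                           (self.pas_count_distribution, "pas_count_distribution")):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        for h in self.hexamer_distribution:
            if len(h) != 6 or not set(h) <= RNA_ALPHABET:
                raise ValueError(f"hexamers must be 6-nt RNA strings, got {h!r}")
        if not 0 <= self.strand_fraction_minus <= 1:
            raise ValueError("strand_fraction_minus must be in [0, 1]")


@dataclass
class CorpusFiles:
    """Paths of one emitted corpus plus its ground truth."""

    fasta: Path
    gff3: Path
    genbank: Path
    truth_tsv: Path
    truth: pd.DataFrame = field(repr=False, default=None)


_PAS_EDGE = 12   # nt between a transcript end and the nearest signal (>= 10)
_PAS_SPACING = 24  # nt between consecutive planted signals


def _revcomp_dna(s: str) -> str:
    return str(Seq(s).reverse_complement())


def generate_corpus(spec: CorpusSpec, outdir, *, gff_dialect: str = "refseq",
                    genbank_dialect: str = "regulatory") -> CorpusFiles:
    """Write a synthetic genome (FASTA) with matching GFF3 and GenBank
    annotation and a ground-truth signal table.

    Each transcript draws a signal count and then that many hexamers i.i.d.
    from the spec's distribution.  Hexamers are planted as DNA inside random
    background sequence (reverse-complemented for minus-strand transcripts,
    whose 5'->3' order runs against the genomic coordinate).  Dialects:
    ``gff_dialect`` 'refseq' (type regulatory_region + regulatory_class
    attribute) or 'so' (type polyA_signal_sequence); ``genbank_dialect``
    'regulatory' (regulatory key + regulatory_class qualifier) or 'legacy'
    (polyA_signal key).
    """
    if gff_dialect not in ("refseq", "so"):
        raise ValueError("gff_dialect must be 'refseq' or 'so'")
    if genbank_dialect not in ("regulatory", "legacy"):
        raise ValueError("genbank_dialect must be 'regulatory' or 'legacy'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    hexamers = list(spec.hexamer_distribution)
    hex_p = np.array([spec.hexamer_distribution[h] for h in hexamers])
    counts = list(spec.pas_count_distribution)
    count_p = np.array([spec.pas_count_distribution[c] for c in counts])

    contigs: list[tuple[str, list[str]]] = []  # (name, mutable seq chars)
    gff_lines = ["##gff-version 3", f"#!pasbind-corpus seed={spec.seed}"]
    gb_records: list[SeqRecord] = []
    truth_rows = []

    n_contigs = math.ceil(spec.n_transcripts / spec.transcripts_per_contig)
    tx_index = 0
    for ci in range(n_contigs):
        contig = f"ctg{ci + 1}"
        n_tx = min(spec.transcripts_per_contig, spec.n_transcripts - tx_index)
        seq_parts: list[str] = []
        features: list[SeqFeature] = []
        cursor = 0  # 0-based length so far
        for _ in range(n_tx):
            tx_index += 1
            tx_id = f"tx{tx_index:06d}"
            n_pas = int(rng.choice(counts, p=count_p))
            tx_hex = [hexamers[i] for i in rng.choice(len(hexamers), size=n_pas, p=hex_p)]
            strand = "-" if rng.random() < spec.strand_fraction_minus else "+"
            tx_len = 2 * _PAS_EDGE + n_pas * 6 + (n_pas - 1) * _PAS_SPACING
            pad = "".join(rng.choice(list("ACGT"), size=spec.intergenic_pad))
            body = list(rng.choice(list("ACGT"), size=tx_len))
            tx_start0 = cursor + spec.intergenic_pad  # 0-based contig offset
            for i, hx in enumerate(tx_hex, start=1):
                # offset of the signal along the transcript (5'->3')
                off = _PAS_EDGE + (i - 1) * (6 + _PAS_SPACING)
                dna = hx.replace("U", "T")
                if strand == "+":
                    g_off = off
                    planted = dna
                else:
                    g_off = tx_len - off - 6
                    planted = _revcomp_dna(dna)
                body[g_off:g_off + 6] = list(planted)
                start1 = tx_start0 + g_off + 1  # 1-based inclusive
                end1 = start1 + 5
                truth_rows.append({
                    "transcript_id": tx_id, "hexamer": hx, "ordinal": i,
                    "n_on_transcript": n_pas, "chrom": contig,
                    "start": start1, "end": end1, "strand": strand,
                })
            seq_parts.append(pad)
            seq_parts.append("".join(body))
            tx_end1 = tx_start0 + tx_len  # 1-based inclusive end
            gff_lines.append(
                f"{contig}\tpasbind\tmRNA\t{tx_start0 + 1}\t{tx_end1}\t.\t{strand}\t.\t"
                f"ID={tx_id};Name={tx_id}"
            )
            loc = SimpleLocation(tx_start0, tx_end1, strand=1 if strand == "+" else -1)
            features.append(SeqFeature(loc, type="mRNA",
                                       qualifiers={"locus_tag": [tx_id], "gene": [tx_id]}))
            for row in truth_rows[-n_pas:]:
                if gff_dialect == "refseq":
                    gff_lines.append(
                        f"{contig}\tpasbind\tregulatory_region\t{row['start']}\t{row['end']}"
                        f"\t.\t{strand}\t.\tID={tx_id}.pas{row['ordinal']};Parent={tx_id};"
                        f"regulatory_class=polyA_signal_sequence"
                    )
                else:
                    gff_lines.append(
                        f"{contig}\tpasbind\tpolyA_signal_sequence\t{row['start']}\t{row['end']}"
                        f"\t.\t{strand}\t.\tID={tx_id}.pas{row['ordinal']};Parent={tx_id}"
                    )
                floc = SimpleLocation(row["start"] - 1, row["end"],
                                      strand=1 if strand == "+" else -1)
                if genbank_dialect == "regulatory":
                    features.append(SeqFeature(
                        floc, type="regulatory",
                        qualifiers={"regulatory_class": ["polyA_signal_sequence"],
                                    "locus_tag": [tx_id]}))
                else:
                    features.append(SeqFeature(floc, type="polyA_signal",
                                               qualifiers={"locus_tag": [tx_id]}))
            cursor = tx_start0 + tx_len
        seq_parts.append("".join(rng.choice(list("ACGT"), size=spec.intergenic_pad)))
        contig_seq = "".join(seq_parts)
        contigs.append((contig, contig_seq))
        rec = SeqRecord(Seq(contig_seq), id=contig, name=contig,
                        description=f"pasbind synthetic contig (seed={spec.seed})")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["comment"] = f"pasbind synthetic corpus, seed={spec.seed}"
        rec.features = features
        gb_records.append(rec)

    fasta_path = outdir / "corpus.fasta"
    with open(fasta_path, "w") as fh:
        for name, seq in contigs:
            fh.write(f">{name} pasbind synthetic corpus seed={spec.seed}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    gff_path = outdir / "corpus.gff3"
    gff_path.write_text("\n".join(gff_lines) + "\n")
    gb_path = outdir / "corpus.gb"
    with open(gb_path, "w") as fh:
        SeqIO.write(gb_records, fh, "genbank")
    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "corpus_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# pasbind synthetic corpus ground truth; seed={spec.seed}\n")
        truth.to_csv(fh, sep="\t", index=False)
    return CorpusFiles(fasta=fasta_path, gff3=gff_path, genbank=gb_path,
                       truth_tsv=truth_path, truth=truth)
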