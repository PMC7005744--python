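"""Synthetic annotation, junction counts, and reads with known truth.

The generator emulates a regulator knockdown/overexpression study: a
panel of multi-exon genes, each with an included and a skipped isoform
of one cassette exon, sequenced under control, knockdown (KD) and
overexpression (OE) conditions.  A designated subset of events is
shifted in PSI, in opposite directions between KD and OE — the
structure the bidirectional screen is designed to recover.

Counts follow the splicing-index estimator's sampling assumptions:
per event and sample the total junction depth is Poisson, inclusion
reads are binomial (optionally beta-binomial) around the true PSI, and
the inclusion total is split evenly at random between the two flanking
junctions.

The genome sequence is synthetic: bases are drawn in short
purine/pyrimidine runs capped at five, so GA-rich windows of width >= 6
never arise by chance and planted GA-rich elements are the only motif
signal.  Real intergenic sequence is not like this; see the methods
notes for what that implies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .junctions import JunctionCountTable

logger = logging.getLogger(__name__)

GA_MOTIF = "GAAGGAGA"
_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the emulated design: two regulators (ADAR1, ADAR2),
    each with a knockdown arm (two shRNA replicates) and an
    overexpression arm (one replicate) against their own controls;
    |dPSI| = 0.3 for shifted events at a mean junction depth of 100
    fragments per event and sample.
    """

    seed: int = 0
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (300, 900)
    n_events_shifted: int = 10
    base_psi: tuple[float, float] = (0.2, 0.8)
    delta_psi: float = 0.3
    depth: float = 100.0
    overdispersion: float = 0.0
    regulators: tuple[str, ...] = ("ADAR1", "ADAR2")
    kd_replicates: int = 2
    oe_replicates: int = 1
    frameshift_fraction: float = 0.5
    motif_plant_fraction: float = 0.66
    ir_bridging_rate: float = 0.05
    read_length: int = 100
    intronic_read_rate: float = 0.02
    chrom_name: str = "simchr1"
    intergenic_gap: int = 600

    def __post_init__(self) -> None:
        lo, hi = self.base_psi
        if not (0 < lo <= hi < 1):
            raise ValueError("base_psi bounds must satisfy 0 < lo <= hi < 1")
        if self.delta_psi <= 0 or self.delta_psi >= 0.96:
            raise ValueError("delta_psi must be in (0, 0.96)")
        if max(0.02 + self.delta_psi, lo) > min(0.98 - self.delta_psi, hi):
            raise ValueError(
                "delta_psi too large for base_psi range: shifted PSIs "
                "cannot stay within [0.02, 0.98]"
            )
        if self.exon_length[0] < 60:
            raise ValueError("exon_length minimum must be >= 60 (read anchors)")
        if self.intron_length[0] < 2 * self.read_length + 20:
            raise ValueError("intron_length minimum too small for read emission")
        if self.n_events_shifted > self.n_genes:
            raise ValueError("n_events_shifted cannot exceed n_genes")

    @property
    def conditions(self) -> list[str]:
        out = ["scr", "ev"]
        for reg in self.regulators:
            out += [f"{reg}-KD", f"{reg}-OE"]
        return out

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(sample_id, condition) pairs."""
        out = [("scr_r1", "scr"), ("ev_r1", "ev")]
        for reg in self.regulators:
            for r in range(1, self.kd_replicates + 1):
                out.append((f"{reg}-KD_r{r}", f"{reg}-KD"))
            for r in range(1, self.oe_replicates + 1):
                out.append((f"{reg}-OE_r{r}", f"{reg}-OE"))
        return out

    @property
    def contrasts(self) -> list[tuple[str, str, str]]:
        """(contrast_id, treatment condition, control condition)."""
        out = []
        for reg in self.regulators:
            out.append((f"{reg}-KD-vs-ctrl", f"{reg}-KD", "scr"))
            out.append((f"{reg}-OE-vs-ctrl", f"{reg}-OE", "ev"))
        return out


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order
    cassette_index: int  # genomic-order index of the cassette exon
    cds_start: int  # genomic coord of start codon first base (sense)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def inclusion_junctions(self) -> list[tuple[int, int]]:
        i = self.cassette_index
        return [
            (self.exons[i - 1][1], self.exons[i][0]),
            (self.exons[i][1], self.exons[i + 1][0]),
        ]

    @property
    def skipping_junction(self) -> tuple[int, int]:
        i = self.cassette_index
        return (self.exons[i - 1][1], self.exons[i + 1][0])

    @property
    def event_id(self) -> str:
        return _event_id_for(self)


@dataclass
class SimTruth:
    """Ground truth: per event and condition the true PSI plus flags."""

    seed: int
    psi: dict[str, dict[str, float]] = field(default_factory=dict)
    shifted: set[str] = field(default_factory=set)
    sign_kd: dict[str, int] = field(default_factory=dict)
    motif_planted: set[str] = field(default_factory=set)
    event_gene: dict[str, str] = field(default_factory=dict)


def _event_id_for(gene: SimGene) -> str:
    (d1, a1), (d2, a2) = gene.inclusion_junctions
    return f"CE:{gene.chrom}:{gene.strand}:{d1}-{a1}:{d2}-{a2}"


def _run_capped_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random DNA with purine and pyrimidine runs both capped at 5."""
    m = n // 2 + 16
    runs = rng.integers(1, 6, size=m)
    while runs.sum() < n:
        runs = np.concatenate([runs, rng.integers(1, 6, size=m)])
    start_class = int(rng.integers(0, 2))
    classes = np.repeat((np.arange(len(runs)) + start_class) % 2, runs)[:n]
    bits = rng.integers(0, 2, size=n)
    # class 0 = purine (A/G), class 1 = pyrimidine (C/T)
    lut = np.array(
        [[ord("A"), ord("G")], [ord("C"), ord("T")]], dtype=np.uint8
    )
    return lut[classes, bits]


def generate_annotation(
    cfg: SimConfig, outdir: Union[str, Path]
) -> tuple[list[SimGene], Path, np.ndarray]:
    """Write the synthetic GTF; return the gene panel and genome sequence.

    The genome FASTA is written by :func:`generate` after motif
    planting (use :func:`_write_fasta` directly when calling this
    stand-alone).

    Each gene carries two isoforms — cassette exon included (.t1, with
    CDS anchors) and skipped (.t2).  A seeded subset of cassette exons
    has length not divisible by three, so skipping them frameshifts.
    GA-rich elements are planted in the transcription-upstream intron
    flank of a seeded subset of shifted events only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes: list[SimGene] = []
    pos = cfg.intergenic_gap
    for g in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if g % 2 == 0 else "-"
        lengths = rng.integers(
            cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons
        )
        cassette = int(rng.integers(1, n_exons - 1))
        frameshifting = rng.random() < cfg.frameshift_fraction
        clen = int(lengths[cassette])
        if frameshifting:
            if clen % 3 == 0:
                clen += 1
        else:
            clen -= clen % 3  # stays >= 60 because the minimum is 60
        lengths[cassette] = clen
        introns = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_exons - 1
        )
        exons = []
        p = pos
        for i, ln in enumerate(lengths):
            exons.append((p, p + int(ln)))
            p += int(ln)
            if i < n_exons - 1:
                p += int(introns[i])
        pos = p + cfg.intergenic_gap
        first = exons[0] if strand == "+" else exons[-1]
        cds_start = first[0] + 10 if strand == "+" else first[1] - 11
        genes.append(
            SimGene(
                gene_id=f"g{g:05d}",
                chrom=cfg.chrom_name,
                strand=strand,
                exons=exons,
                cassette_index=cassette,
                cds_start=cds_start,
            )
        )

    genome_len = pos + cfg.intergenic_gap
    seq = _run_capped_sequence(rng, genome_len)

    # force a start codon at each gene's annotated CDS start (sense strand)
    for gene in genes:
        if gene.strand == "+":
            seq[gene.cds_start : gene.cds_start + 3] = np.frombuffer(
                b"ATG", dtype=np.uint8
            )
        else:
            seq[gene.cds_start - 2 : gene.cds_start + 1] = np.frombuffer(
                b"CAT", dtype=np.uint8
            )

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for gene in genes:
            attrs_t1 = (
                f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
            )
            attrs_t2 = (
                f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t2";'
            )
            for i, (s, e) in enumerate(gene.exons):
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}"
                    f"\t.\t{attrs_t1}\n"
                )
                if i != gene.cassette_index:
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}"
                        f"\t.\t{attrs_t2}\n"
                    )
            if gene.strand == "+":
                sc = (gene.cds_start + 1, gene.cds_start + 3)
            else:
                sc = (gene.cds_start - 1, gene.cds_start + 1)
            fh.write(
                f"{gene.chrom}\tsim\tstart_codon\t{sc[0]}\t{sc[1]}\t.\t"
                f"{gene.strand}\t.\t{attrs_t1}\n"
            )
    return genes, gtf_path, seq


def _write_fasta(seq: np.ndarray, chrom: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        raw = seq.tobytes().decode("ascii")
        for i in range(0, len(raw), 70):
            fh.write(raw[i : i + 70] + "\n")


def make_truth(cfg: SimConfig, genes: list[SimGene]) -> SimTruth:
    """Assign true PSIs per condition and the shifted/sign/motif labels.

    Deterministic in cfg.seed (uses an independent RNG stream so the
    annotation and count draws do not interact with it).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth = SimTruth(seed=cfg.seed)
    shifted_idx = set(
        rng.choice(len(genes), size=cfg.n_events_shifted, replace=False).tolist()
    )
    lo, hi = cfg.base_psi
    s_lo, s_hi = max(0.02 + cfg.delta_psi, lo), min(0.98 - cfg.delta_psi, hi)
    n_motif = int(round(cfg.motif_plant_fraction * cfg.n_events_shifted))
    shifted_order = sorted(shifted_idx)
    motif_idx = set(
        np.asarray(shifted_order)[
            rng.choice(len(shifted_order), size=n_motif, replace=False)
        ].tolist()
        if shifted_order
        else []
    )
    for i, gene in enumerate(genes):
        eid = _event_id_for(gene)
        truth.event_gene[eid] = gene.gene_id
        if i in shifted_idx:
            base = float(rng.uniform(s_lo, s_hi))
            sign = 1 if rng.random() < 0.5 else -1
            truth.shifted.add(eid)
            truth.sign_kd[eid] = sign
            if i in motif_idx:
                truth.motif_planted.add(eid)
        else:
            base = float(rng.uniform(lo, hi))
            sign = 0
        psis = {}
        for cond in cfg.conditions:
            if sign and cond.endswith("-KD"):
                psis[cond] = base + sign * cfg.delta_psi
            elif sign and cond.endswith("-OE"):
                psis[cond] = base - sign * cfg.delta_psi
            else:
                psis[cond] = base
        truth.psi[eid] = psis
    return truth


def plant_motifs(
    genes: list[SimGene], truth: SimTruth, seq: np.ndarray, offset: int = 100
) -> None:
    """Plant the GA-rich element in the transcription-upstream intron flank.

    For plus-strand genes the element lands ``offset`` nt upstream of
    the cassette exon start; for minus-strand genes, the sense-strand
    upstream flank is genomic-downstream of the exon end and the planted
    bases are reverse-complemented.
    """
    motif = np.frombuffer(GA_MOTIF.encode(), dtype=np.uint8)
    motif_rc = np.frombuffer(
        GA_MOTIF.translate(_RC)[::-1].encode(), dtype=np.uint8
    )
    for gene in genes:
        eid = _event_id_for(gene)
        if eid not in truth.motif_planted:
            continue
        s, e = gene.exons[gene.cassette_index]
        if gene.strand == "+":
            start = s - offset - len(motif)
            seq[start : start + len(motif)] = motif
        else:
            start = e + offset
            seq[start : start + len(motif)] = motif_rc


def sample_event_counts(
    rng: np.random.Generator,
    depth: float,
    psi: float,
    overdispersion: float = 0.0,
) -> tuple[int, int]:
    """Draw (inclusion, skipping) fragment counts for one event.

    total ~ Poisson(depth); inclusion ~ Binomial(total, psi), or
    beta-binomial with concentration 1/overdispersion when
    overdispersion > 0.
    """
    total = int(rng.poisson(depth))
    if total == 0:
        return 0, 0
    p = psi
    if overdispersion > 0:
        c = 1.0 / overdispersion
        p = float(rng.beta(max(psi * c, 1e-9), max((1 - psi) * c, 1e-9)))
    inc = int(rng.binomial(total, p))
    return inc, total - inc


def simulate_counts(
    cfg: SimConfig,
    genes: list[SimGene],
    truth: SimTruth,
) -> dict[str, JunctionCountTable]:
    """Per-sample junction count tables implied by the truth PSIs.

    Constitutive junctions draw Poisson(depth) support; cassette
    inclusion fragments split evenly at random between the two flanking
    junctions; intron-retention bridging evidence is emitted at
    ``ir_bridging_rate`` of the event depth on both boundaries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    tables: dict[str, JunctionCountTable] = {}
    for sample_id, cond in cfg.samples:
        table = JunctionCountTable(sample_id=sample_id)
        for gene in genes:
            eid = _event_id_for(gene)
            psi = truth.psi[eid][cond]
            inc, skip = sample_event_counts(
                rng, cfg.depth, psi, cfg.overdispersion
            )
            j_up, j_down = gene.inclusion_junctions
            # each inclusion fragment spans the exon and evidences both
            # flanking junctions: 2*inc junction reads, split evenly at
            # random, so the mean-combined estimate recovers inc exactly
            n_up = int(rng.binomial(2 * inc, 0.5)) if inc else 0
            if n_up:
                table.add_junction(gene.chrom, *j_up, gene.strand, n=n_up)
            if 2 * inc - n_up:
                table.add_junction(gene.chrom, *j_down, gene.strand, n=2 * inc - n_up)
            if skip:
                table.add_junction(
                    gene.chrom, *gene.skipping_junction, gene.strand, n=skip
                )
            cassette_introns = {j_up, j_down}
            for d, a in gene.introns:
                if (d, a) in cassette_introns:
                    continue
                n = int(rng.poisson(cfg.depth))
                if n:
                    table.add_junction(gene.chrom, d, a, gene.strand, n=n)
            if cfg.ir_bridging_rate > 0:
                for d, a in gene.introns:
                    for b in (d, a):
                        n = int(rng.poisson(cfg.depth * cfg.ir_bridging_rate))
                        if n:
                            key = (gene.chrom, b)
                            table.bridging_counts[key] = (
                                table.bridging_counts.get(key, 0) + n
                            )
        tables[sample_id] = table
    return tables


def write_truth(truth: SimTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tgene_id\tcondition\ttrue_psi\tshifted\tsign_kd"
                 "\tmotif_planted\n")
        for eid in sorted(truth.psi):
            for cond, psi in truth.psi[eid].items():
                fh.write(
                    f"{eid}\t{truth.event_gene[eid]}\t{cond}\t{psi:.6g}"
                    f"\t{1 if eid in truth.shifted else 0}"
                    f"\t{truth.sign_kd.get(eid, 0)}"
                    f"\t{1 if eid in truth.motif_planted else 0}\n"
                )


def read_truth(path: Union[str, Path]) -> SimTruth:
    truth = SimTruth(seed=-1)
    with open(path) as fh:
        fh.readline()
        for line in fh:
            eid, gid, cond, psi, shifted, sign, motif = line.rstrip("\n").split("\t")
            truth.psi.setdefault(eid, {})[cond] = float(psi)
            truth.event_gene[eid] = gid
            if shifted == "1":
                truth.shifted.add(eid)
                truth.sign_kd[eid] = int(sign)
            if motif == "1":
                truth.motif_planted.add(eid)
    return truth


def write_sj_tables(
    tables: dict[str, JunctionCountTable], outdir: Union[str, Path]
) -> list[Path]:
    """Emit one STAR-dialect SJ.out.tab per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strand_code = {"+": "1", "-": "2", ".": "0"}
    paths = []
    for sample_id, table in tables.items():
        path = outdir / f"{sample_id}.SJ.out.tab"
        with open(path, "w") as fh:
            for (c, d, a, s), n in sorted(table.junction_counts.items()):
                fh.write(
                    f"{c}\t{d + 1}\t{a}\t{strand_code[s]}\t1\t1\t{n}\t0\t50\n"
                )
        paths.append(path)
    return paths


def emit_sam(
    table: JunctionCountTable,
    genes: list[SimGene],
    seq: np.ndarray,
    cfg: SimConfig,
    path: Union[str, Path],
    seed: int = 0,
) -> None:
    """Write a valid single-end SAM realising the table's junction counts.

    Each junction-supporting fragment becomes one read with a
    half-and-half anchored CIGAR across the gap; bridging counts become
    unspliced reads centred on the boundary; intronic reads are added at
    ``intronic_read_rate`` of depth per intron to exercise
    intron-coverage summaries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    half = cfg.read_length // 2
    raw = seq.tobytes().decode("ascii")
    qual = "I" * cfg.read_length
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{cfg.chrom_name}\tLN:{len(seq)}\n")
        for (chrom, d, a, s), count in sorted(table.junction_counts.items()):
            gap = a - d
            pos = d - half
            cigar = f"{half}M{gap}N{cfg.read_length - half}M"
            read_seq = raw[pos:d] + raw[a : a + cfg.read_length - half]
            for _ in range(count):
                n += 1
                fh.write(
                    f"r{n:08d}\t0\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0"
                    f"\t{read_seq}\t{qual}\n"
                )
        for (chrom, b), count in sorted(table.bridging_counts.items()):
            pos = b - half
            read_seq = raw[pos : pos + cfg.read_length]
            for _ in range(count):
                n += 1
                fh.write(
                    f"r{n:08d}\t0\t{chrom}\t{pos + 1}\t255\t{cfg.read_length}M"
                    f"\t*\t0\t0\t{read_seq}\t{qual}\n"
                )
        if cfg.intronic_read_rate > 0:
            for gene in genes:
                for d, a in gene.introns:
                    k = int(rng.poisson(cfg.depth * cfg.intronic_read_rate))
                    for _ in range(k):
                        start = int(rng.integers(d, a - cfg.read_length + 1))
                        n += 1
                        fh.write(
                            f"r{n:08d}\t0\t{gene.chrom}\t{start + 1}\t255"
                            f"\t{cfg.read_length}M\t*\t0\t0"
                            f"\t{raw[start:start + cfg.read_length]}\t{qual}\n"
                        )


@dataclass
class SimOutput:
    config: SimConfig
    genes: list[SimGene]
    truth: SimTruth
    tables: dict[str, JunctionCountTable]
    gtf: Path
    fasta: Path
    truth_tsv: Path
    sj_dir: Path


def generate(
    cfg: SimConfig, outdir: Union[str, Path], emit_sam_files: bool = False
) -> SimOutput:
    """Run the full generator: annotation, genome, truth, count tables.

    Fully deterministic in cfg.seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, gtf_path, seq = generate_annotation(cfg, outdir)
    fasta_path = outdir / "genome.fa"
    truth = make_truth(cfg, genes)
    plant_motifs(genes, truth, seq)
    _write_fasta(seq, cfg.chrom_name, fasta_path)
    tables = simulate_counts(cfg, genes, truth)
    truth_tsv = outdir / "truth.tsv"
    write_truth(truth, truth_tsv)
    sj_dir = outdir / "sj"
    write_sj_tables(tables, sj_dir)
    if emit_sam_files:
        sam_dir = outdir / "sam"
        sam_dir.mkdir(exist_ok=True)
        for sample_id, table in tables.items():
            emit_sam(
                table, genes, seq, cfg, sam_dir / f"{sample_id}.sam", seed=cfg.seed
            )
    return SimOutput(
        config=cfg,
        genes=genes,
        truth=truth,
        tables=tables,
        gtf=gtf_path,
        fasta=fasta_path,
        truth_tsv=truth_tsv,
        sj_dir=sj_dir,
    )
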