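"""Synthetic data with known ground truth for the amplicon genotyping pipeline.

Generates allele panels, diploid population samples drawn from per-stratum
allele frequencies (with an optional heterozygote-deficit parameter F),
dual-barcoded amplicon reads in random orientation carrying substitution
errors, strand-biased homopolymer deletions and single-crossover PCR
chimeras, and Sanger-style IUPAC consensus sequences.

Every read traces back to a :class:`TruthRecord`, so round-trip tests can
compare pipeline output against exact truth. All randomness flows from one
:class:`numpy.random.Generator`, making output byte-identical for a fixed
seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import IUPAC_PAIR, BarcodePanel, SeqRead, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class AlleleSet:
    """Equal-length, distinct ACGT allele sequences for one locus."""

    locus: str
    names: list[str]
    sequences: list[str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("allele sequences must all have the same length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("allele sequences must be distinct")
        if any(set(s) - set("ACGT") for s in self.sequences):
            raise ValueError("allele alphabet must be ACGT")
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def by_name(self, name: str) -> str:
        return self.sequences[self.names.index(name)]


@dataclass
class ReadProvenance:
    """Per-read ground truth: source allele(s), crossover, injected errors."""

    read_id: str
    source: str | tuple[str, str]
    crossover: int | None = None
    substitutions: list[int] = field(default_factory=list)
    deletions: list[int] = field(default_factory=list)
    orientation: str = "+"

    @property
    def is_chimera(self) -> bool:
        return self.crossover is not None


@dataclass
class TruthRecord:
    """One simulated diploid individual at one locus."""

    sample: str
    stratum: str
    locus: str
    alleles: tuple[str, str]
    reads: list[ReadProvenance] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the sequencing design being emulated: ~350 bp amplicons
    with a 10 forward x 10 reverse panel of exactly 10-bp barcodes, reads in
    either orientation, modest substitution error, PCR chimeras formed by
    single-crossover template switching within a sample, and strand-biased
    single-base deletions in homopolymer runs (length >= 4).
    """

    n_individuals: dict[str, int] = field(default_factory=lambda: {"POP1": 20})
    allele_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    inbreeding_coefficient: float = 0.0
    reads_per_sample: int = 800
    substitution_error_rate: float = 0.001
    chimera_rate: float = 0.05
    homopolymer_indel_rate: float = 0.0
    homopolymer_min_len: int = 4
    read_orientation_prob: float = 0.5
    barcode_hopping_rate: float = 0.0
    base_quality: int = 30
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("inbreeding_coefficient", "substitution_error_rate",
                     "chimera_rate", "homopolymer_indel_rate",
                     "read_orientation_prob", "barcode_hopping_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for stratum, freqs in self.allele_frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"allele frequencies for stratum {stratum} sum to {total}, not 1"
                )


def default_barcode_panel(n_samples: int, rng: np.random.Generator) -> BarcodePanel:
    """Random 10 x 10 panel of distinct 10-bp barcodes covering ``n_samples``."""
    if n_samples > 100:
        raise ValueError("a 10x10 panel covers at most 100 samples")
    barcodes: list[str] = []
    while len(barcodes) < 20:
        bc = "".join(rng.choice(_BASES, size=10))
        if bc not in barcodes:
            barcodes.append(bc)
    fwd, rev = barcodes[:10], barcodes[10:]
    assignments = {}
    for k in range(n_samples):
        assignments[(fwd[k % 10], rev[k // 10])] = f"S{k + 1:03d}"
    return BarcodePanel(forward=fwd, reverse=rev, assignments=assignments)


# ---------------------------------------------------------------------------
# Allele panels
# ---------------------------------------------------------------------------

def gen_allele_set(locus: str, n_alleles: int, length: int, n_variable_sites: int,
                   rng: np.random.Generator, n_triallelic: int = 0) -> AlleleSet:
    """Generate ``n_alleles`` distinct sequences differing at <= ``n_variable_sites``
    columns, optionally forcing ``n_triallelic`` of those columns to carry
    three distinct bases across the panel.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if n_variable_sites > length:
        raise ValueError("n_variable_sites cannot exceed length")
    if n_triallelic > n_variable_sites:
        raise ValueError("n_triallelic cannot exceed n_variable_sites")
    max_distinct = max(2, 3 if n_triallelic else 2) ** max(n_variable_sites, 1)
    if n_alleles > 1 and (n_variable_sites == 0 or n_alleles > max_distinct):
        raise ValueError(
            f"cannot build {n_alleles} distinct alleles from {n_variable_sites} variable sites"
        )
    if n_triallelic and n_alleles < 3:
        raise ValueError("tri-allelic columns need at least 3 alleles")

    backbone = rng.choice(_BASES, size=length)
    if n_alleles == 1:
        return AlleleSet(locus, [f"{locus}*01"], ["".join(backbone)])

    var_cols = np.sort(rng.choice(length, size=n_variable_sites, replace=False))
    for _ in range(1000):
        seqs = np.tile(backbone, (n_alleles, 1))
        for j, col in enumerate(var_cols):
            k = 3 if j < n_triallelic else 2
            states = rng.choice(4, size=k, replace=False)
            # every state must appear at least once across the panel
            assignment = np.concatenate([
                np.arange(k), rng.integers(0, k, size=n_alleles - k)
            ])
            rng.shuffle(assignment)
            seqs[:, col] = _BASES[states[assignment]]
        strings = ["".join(row) for row in seqs]
        if len(set(strings)) == n_alleles:
            names = [f"{locus}*{i + 1:02d}" for i in range(n_alleles)]
            return AlleleSet(locus, names, strings)
    raise RuntimeError("failed to realise distinct alleles; add variable sites")


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def gen_population_genotypes(allele_set: AlleleSet, config: SimConfig,
                             rng: np.random.Generator) -> list[TruthRecord]:
    """Draw diploid genotypes per stratum from the configured frequencies.

    With inbreeding coefficient F, an individual is autozygous with
    probability F (one allele drawn, duplicated), giving
    P(homozygote i) = p_i^2 + F p_i (1 - p_i).
    """
    records: list[TruthRecord] = []
    idx = 0
    for stratum, n in config.n_individuals.items():
        if n <= 0:
            raise ValueError(f"stratum {stratum} has no individuals")
        freqs = config.allele_frequencies.get(stratum)
        if freqs is None:
            freqs = {name: 1.0 / len(allele_set.names) for name in allele_set.names}
        unknown = set(freqs) - set(allele_set.names)
        if unknown:
            raise ValueError(f"frequencies reference unknown alleles: {sorted(unknown)}")
        names = list(freqs)
        probs = np.array([freqs[a] for a in names])
        for _ in range(n):
            idx += 1
            if rng.random() < config.inbreeding_coefficient:
                a = names[rng.choice(len(names), p=probs)]
                pair = (a, a)
            else:
                i, j = rng.choice(len(names), size=2, p=probs)
                pair = (names[i], names[j])
            records.append(TruthRecord(
                sample=f"S{idx:03d}", stratum=stratum,
                locus=allele_set.locus, alleles=pair,
            ))
    return records


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def homopolymer_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs with length >= ``min_len``."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    if rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr), hits.tolist()


def gen_amplicon_reads(truth: list[TruthRecord], allele_set: AlleleSet,
                       config: SimConfig, rng: np.random.Generator,
                       panel: BarcodePanel | None = None
                       ) -> tuple[list[SeqRead], BarcodePanel]:
    """Simulate barcoded amplicon reads, updating truth records in place.

    Each read is forward-barcode + amplicon + revcomp(reverse-barcode),
    reverse-complemented with probability ``read_orientation_prob``. Chimeras
    join one true allele left of a uniform crossover to the other at/after
    it. Homopolymer deletions occur only in runs >= ``homopolymer_min_len``
    and only in reads of one strand, chosen once per run site (modelling the
    strand-limited deletion artefact). Quality strings are constant Phred
    ``base_quality``; errors are realised independently of written quality.
    """
    if not truth:
        raise ValueError("truth is empty")
    if panel is None:
        panel = default_barcode_panel(len(truth), rng)
    sample_to_pair = {s: pair for pair, s in panel.assignments.items()}

    # one strand choice per homopolymer run site, shared across samples
    run_strand = {
        start: ("+" if rng.random() < 0.5 else "-")
        for start, _ in homopolymer_runs(allele_set.sequences[0], config.homopolymer_min_len)
    }

    reads: list[SeqRead] = []
    for rec in truth:
        if rec.sample not in sample_to_pair:
            raise ValueError(f"sample {rec.sample} has no barcode assignment")
        fwd_bc, rev_bc = sample_to_pair[rec.sample]
        a1, a2 = rec.alleles
        s1, s2 = allele_set.by_name(a1), allele_set.by_name(a2)
        for r in range(config.reads_per_sample):
            rid = f"{rec.sample}_r{r + 1:05d}"
            if rng.random() < config.chimera_rate:
                left, right = ((a1, a2) if rng.random() < 0.5 else (a2, a1))
                k = int(rng.integers(1, allele_set.length))
                amplicon = allele_set.by_name(left)[:k] + allele_set.by_name(right)[k:]
                prov = ReadProvenance(rid, (left, right), crossover=k)
            else:
                src = a1 if rng.random() < 0.5 else a2
                amplicon = allele_set.by_name(src)
                prov = ReadProvenance(rid, src)
            prov.orientation = "-" if rng.random() < config.read_orientation_prob else "+"
            # strand-biased homopolymer deletions (applied before substitutions)
            if config.homopolymer_indel_rate > 0:
                dels = []
                for start, length in homopolymer_runs(amplicon, config.homopolymer_min_len):
                    strand = run_strand.get(start, "+")
                    if strand == prov.orientation and rng.random() < config.homopolymer_indel_rate:
                        dels.append(start)
                for start in sorted(dels, reverse=True):
                    amplicon = amplicon[:start] + amplicon[start + 1:]
                prov.deletions = sorted(dels)
            amplicon, subs = _mutate(amplicon, config.substitution_error_rate, rng)
            prov.substitutions = subs
            full = fwd_bc + amplicon + revcomp(rev_bc)
            if prov.orientation == "-":
                full = revcomp(full)
            rec.reads.append(prov)
            reads.append(SeqRead(id=rid, seq=full, qual=[config.base_quality] * len(full)))
    return reads, panel


# ---------------------------------------------------------------------------
# Sanger-style consensus
# ---------------------------------------------------------------------------

def gen_sanger_consensus(truth: TruthRecord, allele_set: AlleleSet) -> SeqRead:
    """IUPAC consensus of the two true alleles (double chromatogram peaks)."""
    s1 = allele_set.by_name(truth.alleles[0])
    s2 = allele_set.by_name(truth.alleles[1])
    if len(s1) != len(s2):
        raise ValueError("alleles of unequal length")
    consensus = "".join(
        a if a == b else IUPAC_PAIR[frozenset((a, b))] for a, b in zip(s1, s2)
    )
    return SeqRead(id=truth.sample, seq=consensus)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstratum\tlocus\tallele1\tallele2\n")
        for rec in truth:
            fh.write(f"{rec.sample}\t{rec.stratum}\t{rec.locus}\t"
                     f"{rec.alleles[0]}\t{rec.alleles[1]}\n")


def simulate_dataset(allele_set: AlleleSet, config: SimConfig, outdir=None):
    """Convenience wrapper: genotypes + reads (+ files when ``outdir`` given)."""
    rng = np.random.default_rng(config.rng_seed)
    truth = gen_population_genotypes(allele_set, config, rng)
    reads, panel = gen_amplicon_reads(truth, allele_set, config, rng)
    if outdir is not None:
        from .io import write_barcode_panel, write_fasta, write_fastq
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, outdir / "reads.fastq")
        write_truth_tsv(truth, outdir / "truth.tsv")
        write_fasta(
            [SeqRead(id=n, seq=s) for n, s in zip(allele_set.names, allele_set.sequences)],
            outdir / "alleles.fasta",
        )
        write_barcode_panel(panel, outdir / "barcodes.tsv")
    return truth, reads, panel
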