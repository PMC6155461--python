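"""Sequence I/O, barcode panels, VCF output, run manifests and logging.

All standard-format parsing goes through Biopython's :mod:`Bio.SeqIO`; this
module adds validation (alphabet, quality/sequence length agreement), the
simple TSV formats used across the pipeline, and a minimal VCF 4.2 writer.
Internal coordinates are 0-based half-open; VCF output is 1-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger("mhcamplicon")

#: IUPAC nucleotide codes accepted on input (aligned FASTA may also carry '-').
IUPAC_CODES = set("ACGTNRYSWKMBDHV")

#: Two-base ambiguity codes used for heterozygous Sanger positions.
IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRead:
    """A sequencing read (or plain sequence record).

    ``strand`` records the original orientation observed before any
    orientation normalisation ('+' as sequenced forward, '-' if the read was
    reverse-complemented during demultiplexing). ``sample`` is filled in by
    the demultiplexer.
    """

    id: str
    seq: str
    qual: list[int] | None = None
    strand: str = "+"
    sample: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


class SequenceFormatError(ValueError):
    """Malformed sequence record (bad alphabet, length mismatch...)."""


def _validate_seq(rec_id: str, seq: str, allow_gaps: bool) -> str:
    up = seq.upper()
    if up != seq:
        log.warning("record %s contains lowercase bases; uppercased", rec_id)
    allowed = IUPAC_CODES | ({"-"} if allow_gaps else set())
    for i, base in enumerate(up):
        if base not in allowed:
            raise SequenceFormatError(
                f"record {rec_id}: invalid character {base!r} at position {i}"
            )
    return up


def read_sequences(path, fmt: str | None = None, allow_gaps: bool = False) -> list[SeqRead]:
    """Read FASTA/FASTQ records with validation.

    ``fmt`` is inferred from the file suffix when not given. Lowercase bases
    are uppercased with a warning; characters outside the IUPAC alphabet
    (plus '-' when ``allow_gaps``) raise :class:`SequenceFormatError` naming
    the record and position. FASTQ quality/sequence length mismatches are
    rejected by the underlying parser.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    out: list[SeqRead] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = _validate_seq(rec.id, str(rec.seq), allow_gaps)
            qual = rec.letter_annotations.get("phred_quality")
            out.append(SeqRead(id=rec.id, seq=seq, qual=list(qual) if qual else None))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise SequenceFormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None or len(rec.qual) != len(rec.seq):
                raise SequenceFormatError(
                    f"record {rec.id}: quality/sequence length mismatch"
                )
            qstr = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Barcode panels
# ---------------------------------------------------------------------------

@dataclass
class BarcodePanel:
    """Dual 10-bp barcode panel mapping (forward, reverse) pairs to samples.

    Library construction attaches one barcode at each amplicon end, so a
    panel of 10 forward x 10 reverse barcodes covers up to 100 samples.
    """

    forward: list[str]
    reverse: list[str]
    assignments: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for bc in list(self.forward) + list(self.reverse):
            if len(bc) != 10:
                raise ValueError(f"barcode {bc} is not exactly 10 bp")
        if len(set(self.forward)) != len(self.forward) or len(set(self.reverse)) != len(self.reverse):
            raise ValueError("duplicate barcode sequences in panel")
        for (f, r), sample in self.assignments.items():
            if f not in self.forward or r not in self.reverse:
                raise ValueError(f"assignment for {sample} uses unknown barcode")


def read_barcode_panel(path) -> BarcodePanel:
    """Read a barcode panel TSV: ``sample<TAB>forward<TAB>reverse`` rows."""
    fwd, rev, assignments = [], [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("sample\t"):
                continue
            sample, f, r = line.split("\t")[:3]
            if f not in fwd:
                fwd.append(f)
            if r not in rev:
                rev.append(r)
            assignments[(f, r)] = sample
    return BarcodePanel(forward=fwd, reverse=rev, assignments=assignments)


def write_barcode_panel(panel: BarcodePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tforward\treverse\n")
        for (f, r), sample in panel.assignments.items():
            fh.write(f"{sample}\t{f}\t{r}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_variants(calls, reference: str, path, locus: str = "locus", sample: str = "SAMPLE") -> None:
    """Write reconciled calls as a minimal VCF 4.2 file.

    ``calls`` are :class:`mhcamplicon.caller.VariantCall` objects with 0-based
    positions; output positions are 1-based. Multi-allelic ALTs are emitted
    comma-separated and genotypes are phased ('|') since they come from the
    read-backed phaser. INFO carries caller provenance and the reconciliation
    class.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus},length={len(reference)}>",
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling route: ratio, likelihood or both">',
        '##INFO=<ID=RECON,Number=1,Type=String,Description="Reconciliation status/class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for call in calls:
        if not 0 <= call.pos < len(reference):
            raise ValueError(f"call position {call.pos} outside reference")
        ref = reference[call.pos]
        alts = [b for b in call.genotype if b != ref]
        # preserve order, dedupe
        seen: list[str] = []
        for b in alts:
            if b not in seen:
                seen.append(b)
        if not seen:
            continue
        alleles = [ref] + seen
        gt = "|".join(str(alleles.index(b)) for b in call.genotype)
        qual = f"{call.qual:.0f}" if call.qual is not None else "."
        info = f"CALLER={call.caller};RECON={call.status}"
        lines.append(
            f"{locus}\t{call.pos + 1}\t.\t{ref}\t{','.join(seen)}\t{qual}\tPASS\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Manifest / logging
# ---------------------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, parameters: dict, inputs: dict | None = None) -> None:
    """Write a machine-readable run manifest (parameters, seed, input hashes)."""
    manifest = {
        "parameters": parameters,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mhcamplicon")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper()))
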