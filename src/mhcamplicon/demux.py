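"""Length filtering, exact dual-barcode demultiplexing and per-sample QC.

Reads are first length-filtered (default: keep >= 350 bp, allowing for
deletions in full-length amplicons), then assigned to samples iff the first
10 bp exactly match a forward barcode and the last 10 bp exactly match the
reverse complement of a reverse barcode, testing both read orientations.
Assigned reads are orientation-normalised, trimmed of exactly 10 bp at each
end, and tallied. Reads matching a barcode combination not mapped to any
sample accumulate in an unused-combination tally whose maximum serves as a
contamination benchmark. Samples below the read-count cutoff (default 500)
are excluded from genotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io import BarcodePanel, SeqRead, revcomp

log = logging.getLogger("mhcamplicon")

BARCODE_LEN = 10


@dataclass
class DemuxReport:
    total_reads: int = 0
    reads_passing_length: int = 0
    reads_with_perfect_barcodes: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)
    unused_combinations: dict[tuple[str, str], int] = field(default_factory=dict)
    unassigned: int = 0
    excluded_samples: list[str] = field(default_factory=list)
    min_reads: int | None = None

    @property
    def unused_benchmark(self) -> int:
        """Highest read count over unused barcode combinations."""
        return max(self.unused_combinations.values(), default=0)

    def check_partition(self) -> bool:
        assigned = sum(self.per_sample.values())
        unused = sum(self.unused_combinations.values())
        return assigned + unused + self.unassigned == self.reads_passing_length

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"total_reads\t{self.total_reads}\n")
            fh.write(f"reads_passing_length\t{self.reads_passing_length}\n")
            fh.write(f"reads_with_perfect_barcodes\t{self.reads_with_perfect_barcodes}\n")
            fh.write(f"unassigned\t{self.unassigned}\n")
            fh.write(f"unused_benchmark\t{self.unused_benchmark}\n")
            for sample, n in sorted(self.per_sample.items()):
                fh.write(f"sample:{sample}\t{n}\n")
            for (f, r), n in sorted(self.unused_combinations.items()):
                fh.write(f"unused:{f}+{r}\t{n}\n")
            for sample in self.excluded_samples:
                fh.write(f"excluded:{sample}\t\n")


def filter_length(reads: list[SeqRead], min_len: int = 350) -> list[SeqRead]:
    """Keep reads with length >= ``min_len``."""
    return [r for r in reads if len(r) >= min_len]


def _match(seq: str, fwd_set: frozenset, rev_rc: dict) -> tuple[str, str] | None:
    head, tail = seq[:BARCODE_LEN], seq[-BARCODE_LEN:]
    if head in fwd_set and tail in rev_rc:
        return head, rev_rc[tail]
    return None


def demultiplex(reads: list[SeqRead], panel: BarcodePanel,
                report: DemuxReport | None = None
                ) -> tuple[dict[str, list[SeqRead]], DemuxReport]:
    """Assign reads to samples by exact dual barcodes (0 mismatches).

    Both orientations are tested; assigned reads are emitted in forward
    orientation with barcodes trimmed, carrying their original strand in
    ``SeqRead.strand``.
    """
    if report is None:
        report = DemuxReport()
    report.reads_passing_length += len(reads)
    fwd_set = frozenset(panel.forward)
    rev_rc = {revcomp(bc): bc for bc in panel.reverse}
    per_sample: dict[str, list[SeqRead]] = {s: [] for s in panel.assignments.values()}

    for read in reads:
        if len(read) < 2 * BARCODE_LEN + 1:
            report.unassigned += 1
            continue
        hit = _match(read.seq, fwd_set, rev_rc)
        strand = "+"
        seq, qual = read.seq, read.qual
        if hit is None:
            seq = revcomp(read.seq)
            qual = read.qual[::-1] if read.qual else None
            hit = _match(seq, fwd_set, rev_rc)
            strand = "-"
        if hit is None:
            report.unassigned += 1
            continue
        report.reads_with_perfect_barcodes += 1
        sample = panel.assignments.get(hit)
        if sample is None:
            report.unused_combinations[hit] = report.unused_combinations.get(hit, 0) + 1
            continue
        trimmed = replace(
            read,
            seq=seq[BARCODE_LEN:-BARCODE_LEN],
            qual=qual[BARCODE_LEN:-BARCODE_LEN] if qual else None,
            strand=strand,
            sample=sample,
        )
        per_sample[sample].append(trimmed)
        report.per_sample[sample] = report.per_sample.get(sample, 0) + 1
    return per_sample, report


def sample_qc(per_sample: dict[str, list[SeqRead]], report: DemuxReport,
              min_reads: int = 500) -> dict[str, list[SeqRead]]:
    """Exclude samples with fewer than ``min_reads`` reads, logging each.

    The report keeps the maximum unused-combination count as the
    contamination benchmark against which the cutoff can be judged.
    """
    report.min_reads = min_reads
    retained = {}
    for sample, reads in per_sample.items():
        if len(reads) >= min_reads:
            retained[sample] = reads
        else:
            report.excluded_samples.append(sample)
            log.info("sample %s excluded: %d reads < %d", sample, len(reads), min_reads)
    if report.unused_combinations:
        log.info("unused-combination background benchmark: %d reads",
                 report.unused_benchmark)
    return retained


def run_demux(reads: list[SeqRead], panel: BarcodePanel, min_len: int = 350,
              min_reads: int = 500) -> tuple[dict[str, list[SeqRead]], DemuxReport]:
    """Length filter -> demultiplex -> sample QC, in pipeline order."""
    report = DemuxReport(total_reads=len(reads))
    kept = filter_length(reads, min_len)
    per_sample, report = demultiplex(kept, panel, report)
    retained = sample_qc(per_sample, report, min_reads)
    return retained, report
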