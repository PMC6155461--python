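"""Allele catalogues, sample genotyping and Sanger-consensus resolution.

Phased haplotypes from many samples are collapsed into a named allele
catalogue: identical haplotypes merge, names are assigned in descending
frequency (``<Taxon4>-<Locus><P?>*NN``), coding haplotypes whose translation
contains a stop codon are excluded as non-functional, and an allele is
``confirmed`` only when supported by at least two individuals or an
independent method (otherwise ``provisional``).

Sanger IUPAC consensus sequences are resolved against known alleles with
parsimonious logic: prefer a pair of known alleles whose position-wise union
reproduces the consensus; failing that, infer at most one novel allele as
the unique position-wise complement of a compatible known allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io import IUPAC_EXPAND, IUPAC_PAIR, SeqRead

log = logging.getLogger("mhcamplicon")


@dataclass
class AlleleRecord:
    name: str
    sequence: str
    support: int                      # number of supporting individuals
    status: str                       # confirmed | provisional
    cross_method: int = 0             # independent-method confirmations


@dataclass
class AlleleCatalogue:
    locus: str
    records: list[AlleleRecord] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # stop-codon haplotypes

    def name_of(self, sequence: str) -> str:
        for rec in self.records:
            if rec.sequence == sequence:
                return rec.name
        raise KeyError("haplotype absent from catalogue")

    def by_name(self, name: str) -> AlleleRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)


class UnresolvableError(ValueError):
    """No known allele is compatible with the consensus; cloning required."""


class AmbiguousGenotypeError(ValueError):
    """Multiple equally parsimonious solutions; refusing to guess."""


def _has_stop(sequence: str, trim: tuple[int, int]) -> bool:
    head, tail = trim
    coding = sequence[head:len(sequence) - tail]
    if len(coding) % 3:
        raise ValueError("post-trim length not divisible by 3")
    return "*" in str(Seq(coding).translate())


def build_catalogue(phased_pairs: dict[str, tuple[str, str]], locus: str,
                    taxon: str = "Tutr", coding: bool = False,
                    trim: tuple[int, int] = (2, 1),
                    cross_method: dict[str, int] | None = None) -> AlleleCatalogue:
    """Collapse per-sample phased haplotype pairs into a named catalogue.

    ``coding`` loci are translated after trimming the partial codon
    (``trim`` = bases removed from the start/end); stop-bearing haplotypes
    are flagged invalid and excluded. ``cross_method`` maps haplotype
    sequences to counts of independent-method confirmations, which can
    confirm single-individual alleles.
    """
    if not phased_pairs:
        raise ValueError("no phased pairs supplied")
    lengths = {len(h) for pair in phased_pairs.values() for h in pair}
    if len(lengths) > 1:
        raise ValueError("haplotypes differ in length")
    support: dict[str, int] = {}
    for pair in phased_pairs.values():
        for hap in set(pair):  # a homozygote supports its allele once
            support[hap] = support.get(hap, 0) + 1
    cross_method = cross_method or {}
    catalogue = AlleleCatalogue(locus=locus)
    kept = []
    for hap, n in support.items():
        if coding and _has_stop(hap, trim):
            catalogue.excluded.append(hap)
            log.warning("%s: haplotype excluded, translation contains a stop codon", locus)
            continue
        kept.append((hap, n))
    kept.sort(key=lambda item: (-item[1], item[0]))
    for i, (hap, n) in enumerate(kept, start=1):
        xm = cross_method.get(hap, 0)
        status = "confirmed" if (n >= 2 or xm >= 1) else "provisional"
        catalogue.records.append(AlleleRecord(
            name=f"{taxon}-{locus}*{i:02d}", sequence=hap,
            support=n, status=status, cross_method=xm,
        ))
    return catalogue


def genotype_samples(catalogue: AlleleCatalogue,
                     phased_pairs: dict[str, tuple[str, str]],
                     strata: dict[str, str] | None = None) -> list[dict]:
    """Map each sample's haplotype pair to an ordered allele-name pair."""
    rows = []
    for sample, (h1, h2) in phased_pairs.items():
        try:
            names = sorted((catalogue.name_of(h1), catalogue.name_of(h2)))
        except KeyError as exc:
            raise KeyError(f"sample {sample}: haplotype absent from catalogue") from exc
        rows.append({
            "sample": sample,
            "stratum": (strata or {}).get(sample, "NA"),
            "locus": catalogue.locus,
            "allele1": names[0],
            "allele2": names[1],
        })
    return rows


def write_genotype_tsv(rows: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tstratum\tlocus\tallele1\tallele2\n")
        for row in rows:
            fh.write(f"{row['sample']}\t{row['stratum']}\t{row['locus']}\t"
                     f"{row['allele1']}\t{row['allele2']}\n")


def write_catalogue(catalogue: AlleleCatalogue, fasta_path, tsv_path) -> None:
    from .io import write_fasta
    write_fasta([SeqRead(id=r.name, seq=r.sequence) for r in catalogue.records],
                fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("name\tsequence\tsupport\tstatus\n")
        for r in catalogue.records:
            fh.write(f"{r.name}\t{r.sequence}\t{r.support}\t{r.status}\n")


# ---------------------------------------------------------------------------
# Sanger consensus resolution
# ---------------------------------------------------------------------------

def _pair_union(a: str, b: str) -> str:
    return "".join(
        x if x == y else IUPAC_PAIR[frozenset((x, y))] for x, y in zip(a, b)
    )


def _compatible(allele: str, consensus: str) -> bool:
    return all(a in IUPAC_EXPAND[c] for a, c in zip(allele, consensus))


def resolve_sanger_genotype(consensus: str, known: dict[str, str],
                            support: dict[str, int] | None = None):
    """Resolve an IUPAC diploid consensus against known alleles.

    Returns ``(name1, name2, novel_sequence_or_None)``. Solutions are ranked
    by parsimony: zero novel alleles beat one; two novel alleles are never
    inferred. Among multiple zero-novel pairs, the pair with the largest
    summed catalogue ``support`` wins (frequency-weighted preference); an
    unresolvable tie, or multiple distinct one-novel complements, raises.
    """
    consensus = consensus.upper()
    if any(len(IUPAC_EXPAND.get(c, "")) > 2 or c not in IUPAC_EXPAND for c in consensus):
        raise ValueError("consensus may only contain bases and 2-base ambiguity codes")
    names = list(known)
    for name in names:
        if len(known[name]) != len(consensus):
            raise ValueError(f"allele {name} length differs from consensus")

    # exact known pairs whose position-wise union equals the consensus
    matches = [
        (names[i], names[j])
        for i in range(len(names)) for j in range(i, len(names))
        if _pair_union(known[names[i]], known[names[j]]) == consensus
    ]
    if matches:
        if len(matches) == 1:
            a, b = matches[0]
            return a, b, None
        if support:
            scored = sorted(
                matches,
                key=lambda pair: -(support.get(pair[0], 0) + support.get(pair[1], 0)),
            )
            best = support.get(scored[0][0], 0) + support.get(scored[0][1], 0)
            second = support.get(scored[1][0], 0) + support.get(scored[1][1], 0)
            if best > second:
                log.info("consensus matched %d pairs; frequency-weighted choice %s",
                         len(matches), scored[0])
                return scored[0][0], scored[0][1], None
        raise AmbiguousGenotypeError(
            f"consensus compatible with {len(matches)} known pairs with equal support"
        )

    # one-novel solutions: the complement of a compatible known allele is
    # forced position-wise (the other base at 2-base codes)
    solutions: dict[str, str] = {}  # novel sequence -> known partner name
    for name in names:
        allele = known[name]
        if not _compatible(allele, consensus):
            continue
        novel = []
        for a, c in zip(allele, consensus):
            bases = IUPAC_EXPAND[c]
            novel.append(a if len(bases) == 1 else bases.replace(a, ""))
        novel_seq = "".join(novel)
        if novel_seq not in known.values():
            solutions.setdefault(novel_seq, name)
    if not solutions:
        raise UnresolvableError("no known allele compatible; cloning required")
    if len(solutions) > 1:
        raise AmbiguousGenotypeError(
            f"{len(solutions)} distinct one-novel solutions; refusing to predict"
        )
    novel_seq, partner = next(iter(solutions.items()))
    return partner, None, novel_seq
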