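"""5'-tRF annotation reference.

Builds, from a genome and a set of tRNA gene models, the two sequence sets
used for read accounting — mature tRNA sequences (introns excised, CCA
appended at the 3' end) and pre-tRNA sequences (introns retained, genomic
leader/trailer flanks, no CCA) — and enumerates the deduplicated candidate
5'-tRF set: all mature-sequence prefixes inside a length window.

5'-tRFs are defined here as fragments anchored at mature position 1 whose
3' ends range over a length window (default 14-32 nt), which spans the
reported 5'-tRF size range while excluding 5' tRNA halves.  Candidates are
enumerated from mature (CCA-appended) sequences only; pre-tRNA sequences
exist in the reference for the read-accounting denominator.

Coordinate conventions: BED input is 0-based half-open; the internal gene
model is 1-based inclusive.  Intron intervals are 1-based inclusive
positions within the gene's genomic span, counted from the gene start on
the genome's plus strand.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TRNAGene:
    """A tRNA gene model on a genome (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    anticodon: str
    amino_acid: str = ""
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    source: str = "nuclear"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be a 3-mer")
        length = self.end - self.start + 1
        for a, b in self.intron_intervals:
            if not (1 <= a <= b <= length):
                raise ValueError(f"{self.gene_id}: intron ({a},{b}) outside gene of length {length}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TRFCandidate:
    """A deduplicated candidate 5'-tRF sequence with parent provenance."""

    trf_id: str
    sequence: str
    length: int
    parent_gene_ids: frozenset[str]
    anchor: str = "mature-5prime"
    parent_contexts: str = "mature"


@dataclass
class TRFReference:
    """The full annotation database used for quantification."""

    candidates: list[TRFCandidate]
    mature_sequences: dict[str, str]
    pre_trna_sequences: dict[str, str]
    build_parameters: dict

    def __post_init__(self) -> None:
        self._by_sequence = {c.sequence: c for c in self.candidates}
        if len(self._by_sequence) != len(self.candidates):
            raise ValueError("candidate sequences are not pairwise distinct")

    def candidate_by_sequence(self, seq: str) -> TRFCandidate | None:
        return self._by_sequence.get(seq)

    @property
    def candidate_sequences(self) -> set[str]:
        return set(self._by_sequence)

    def write(self, outdir: str | Path) -> None:
        """Write candidate FASTA, provenance TSV and a JSON build manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "candidates.fa", "w") as fh:
            for c in self.candidates:
                fh.write(f">{c.trf_id}\n{c.sequence}\n")
        rows = [
            {
                "trf_id": c.trf_id,
                "sequence": c.sequence,
                "length": c.length,
                "parent_genes": ",".join(sorted(c.parent_gene_ids)),
            }
            for c in self.candidates
        ]
        pd.DataFrame(rows).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        for name, seqs in (("mature.fa", self.mature_sequences),
                           ("pre_trna.fa", self.pre_trna_sequences)):
            with open(outdir / name, "w") as fh:
                for gene_id in sorted(seqs):
                    fh.write(f">{gene_id}\n{seqs[gene_id]}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.build_parameters, fh, indent=2, sort_keys=True)


def _gene_genomic_slice(gene: TRNAGene, genome: dict[str, str]) -> str:
    if gene.chrom not in genome:
        raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom]
    if gene.start < 1 or gene.end > len(chrom_seq):
        raise ValueError(f"{gene.gene_id}: coordinates outside chromosome bounds")
    return chrom_seq[gene.start - 1 : gene.end].upper()


def build_mature_sequences(genes: list[TRNAGene], genome: dict[str, str]) -> dict[str, str]:
    """Mature tRNA sequences: introns excised, strand-corrected, CCA appended."""
    out: dict[str, str] = {}
    for gene in genes:
        body = _gene_genomic_slice(gene, genome)
        keep = bytearray(len(body))
        for i in range(len(body)):
            keep[i] = 1
        for a, b in gene.intron_intervals:
            for i in range(a - 1, b):
                keep[i] = 0
        spliced = "".join(ch for ch, k in zip(body, keep) if k)
        if gene.strand == "-":
            spliced = reverse_complement(spliced)
        out[gene.gene_id] = spliced + "CCA"
    return out


def build_pre_trna_sequences(
    genes: list[TRNAGene], genome: dict[str, str], flank: int = 50
) -> dict[str, str]:
    """Pre-tRNA sequences: genomic gene sequence with introns retained and
    5' leader / 3' trailer of ``flank`` nt, strand-corrected, no CCA.

    Flanks are truncated at chromosome ends.
    """
    out: dict[str, str] = {}
    for gene in genes:
        chrom_seq = genome[gene.chrom] if gene.chrom in genome else None
        if chrom_seq is None:
            raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
        if gene.start < 1 or gene.end > len(chrom_seq):
            raise ValueError(f"{gene.gene_id}: coordinates outside chromosome bounds")
        lo = max(1, gene.start - flank)
        hi = min(len(chrom_seq), gene.end + flank)
        seq = chrom_seq[lo - 1 : hi].upper()
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out[gene.gene_id] = seq
    return out


def _trf_id(parent_ids: frozenset[str], length: int) -> str:
    digest = hashlib.sha1(
        (",".join(sorted(parent_ids)) + f":{length}").encode()
    ).hexdigest()[:10]
    return f"tRF5-L{length:02d}-{digest}"


def enumerate_5ptrf_candidates(
    mature_sequences: dict[str, str],
    length_bounds: tuple[int, int] = (14, 32),
    pre_trna_sequences: dict[str, str] | None = None,
    flank: int = 50,
) -> TRFReference:
    """Enumerate and deduplicate all 5'-anchored mature prefixes.

    For each mature sequence all prefixes of length Lmin..Lmax are emitted
    (shorter matures contribute prefixes up to their own length); identical
    sequences are collapsed into one candidate whose parent set is the
    union of the contributing genes.
    """
    lmin, lmax = length_bounds
    if lmin > lmax:
        raise ValueError(f"Lmin {lmin} > Lmax {lmax}")
    if lmin < 8:
        raise ValueError("Lmin must be >= 8")
    parents_by_seq: dict[str, set[str]] = {}
    for gene_id, mature in mature_sequences.items():
        top = min(lmax, len(mature))
        for L in range(lmin, top + 1):
            parents_by_seq.setdefault(mature[:L], set()).add(gene_id)
    candidates = []
    for seq in sorted(parents_by_seq, key=lambda s: (len(s), s)):
        parents = frozenset(parents_by_seq[seq])
        candidates.append(
            TRFCandidate(
                trf_id=_trf_id(parents, len(seq)),
                sequence=seq,
                length=len(seq),
                parent_gene_ids=parents,
            )
        )
    return TRFReference(
        candidates=candidates,
        mature_sequences=dict(mature_sequences),
        pre_trna_sequences=dict(pre_trna_sequences or {}),
        build_parameters={"lmin": lmin, "lmax": lmax, "flank": flank},
    )


def build_reference(
    genes: list[TRNAGene],
    genome: dict[str, str],
    length_bounds: tuple[int, int] = (14, 32),
    flank: int = 50,
) -> TRFReference:
    """Convenience wrapper: mature + pre-tRNA sequences + candidate set."""
    mature = build_mature_sequences(genes, genome)
    pre = build_pre_trna_sequences(genes, genome, flank=flank)
    return enumerate_5ptrf_candidates(
        mature, length_bounds=length_bounds, pre_trna_sequences=pre, flank=flank
    )


# ---------------------------------------------------------------------------
# I/O: BED and gene-table readers
# ---------------------------------------------------------------------------

def genes_to_bed(genes: list[TRNAGene], path: str | Path) -> None:
    """Write genes as BED12 (0-based half-open; introns via block fields)."""
    with open(path, "w") as fh:
        for g in genes:
            chrom_start = g.start - 1
            chrom_end = g.end
            # blocks = exonic pieces between introns, in genomic order
            cuts = sorted(g.intron_intervals)
            blocks: list[tuple[int, int]] = []  # 0-based offsets within gene
            pos = 0
            for a, b in cuts:
                if a - 1 > pos:
                    blocks.append((pos, a - 1))
                pos = b
            if pos < g.length:
                blocks.append((pos, g.length))
            sizes = ",".join(str(b - a) for a, b in blocks)
            starts = ",".join(str(a) for a, _ in blocks)
            name = f"{g.gene_id}|{g.anticodon}|{g.amino_acid}|{g.source}"
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom,
                            chrom_start,
                            chrom_end,
                            name,
                            0,
                            g.strand,
                            chrom_start,
                            chrom_end,
                            "0,0,0",
                            len(blocks),
                            sizes,
                            starts,
                        ],
                    )
                )
                + "\n"
            )


def genes_from_bed(path: str | Path) -> list[TRNAGene]:
    """Read tRNA genes from BED (6- or 12-column; blocks encode introns)."""
    genes: list[TRNAGene] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, cstart, cend, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            fields = name.split("|")
            gene_id = fields[0]
            anticodon = fields[1] if len(fields) > 1 else "NNN"
            amino_acid = fields[2] if len(fields) > 2 else ""
            source = fields[3] if len(fields) > 3 else "nuclear"
            introns: list[tuple[int, int]] = []
            if len(parts) >= 12 and int(parts[9]) > 1:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                for i in range(len(sizes) - 1):
                    intron_a = starts[i] + sizes[i] + 1  # 1-based inclusive
                    intron_b = starts[i + 1]
                    introns.append((intron_a, intron_b))
            genes.append(
                TRNAGene(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=cstart + 1,
                    end=cend,
                    anticodon=anticodon,
                    amino_acid=amino_acid,
                    intron_intervals=introns,
                    source=source,
                )
            )
    return genes
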