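"""Readers and writers for the pipeline's plain-text formats.

Conventions: tag libraries are 2-column TSV (tag, count); annotations are
2-column TSV (gene_id, term); coordinates are 0-based half-open; sequences
travel as FASTA via Biopython; distance matrices as PHYLIP square matrices;
trees as newick.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylogeny import DistanceMatrix, ProteinAlignment
from .types import AnnotationMap, SyntheticReference, TagLibrary


# -- FASTA ------------------------------------------------------------------

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_reference(ref: SyntheticReference, outdir: str | Path, prefix: str = "ref") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / f"{prefix}_transcripts.fasta", ref.transcripts)
    write_fasta(outdir / f"{prefix}_genome.fasta", {"genome": ref.genome})
    rows = [(g, s, e) for g, (s, e) in sorted(ref.coordinates.items())]
    pd.DataFrame(rows, columns=["gene_id", "start", "end"]).to_csv(
        outdir / f"{prefix}_coords.tsv", sep="\t", index=False
    )


def read_reference(outdir: str | Path, prefix: str = "ref") -> SyntheticReference:
    from .simulate import canonical_tag

    outdir = Path(outdir)
    transcripts = read_fasta(outdir / f"{prefix}_transcripts.fasta")
    genome = read_fasta(outdir / f"{prefix}_genome.fasta")["genome"]
    coords = {
        r.gene_id: (int(r.start), int(r.end))
        for r in pd.read_csv(outdir / f"{prefix}_coords.tsv", sep="\t").itertuples()
    }
    genes = [(g, transcripts[g]) for g in sorted(transcripts)]
    tags = {g: canonical_tag(t) for g, t in genes}
    return SyntheticReference(genes=genes, genome=genome, coordinates=coords, canonical_tags=tags)


# -- tag libraries ----------------------------------------------------------

def write_tags(path: str | Path, tags: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for t in sorted(tags):
            fh.write(f"{t}\t{tags[t]}\n")


def read_tags(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return dict(zip(df["tag"], df["count"]))


def write_library(lib: TagLibrary, path: str | Path, which: str = "raw") -> None:
    write_tags(path, getattr(lib, which))


def read_library(
    path: str | Path,
    library_id: Optional[str] = None,
    stage: str = "other",
    strain: str = "",
    which: str = "raw",
) -> TagLibrary:
    tags = read_tags(path)
    lid = library_id if library_id is not None else Path(path).stem
    lib = TagLibrary(library_id=lid, stage=stage, strain=strain)
    setattr(lib, which, tags)
    return lib


# -- annotations ------------------------------------------------------------

def write_annotation(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm\n")
        for g in sorted(ann.gene_terms):
            for t in sorted(ann.gene_terms[g]):
                fh.write(f"{g}\t{t}\n")


def read_annotation(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_terms: dict[str, set[str]] = {}
    for r in df.itertuples():
        gene_terms.setdefault(r.gene_id, set()).add(r.term)
    return AnnotationMap(gene_terms)


# -- alignments & trees -----------------------------------------------------

def write_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    write_fasta(path, dict(zip(aln.taxa, aln.rows)))


def read_alignment(path: str | Path) -> ProteinAlignment:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return ProteinAlignment([t for t, _ in records], [s for _, s in records])


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance matrix (names padded to 10 characters)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, t in enumerate(dm.taxa):
            row = " ".join(f"{v:.6f}" for v in dm.d[i])
            fh.write(f"{t[:10]:<10} {row}\n")
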