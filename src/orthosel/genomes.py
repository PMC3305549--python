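"""Genome containers: named genomes of paired protein/CDS gene records.

The ortholog-detection stage consumes a :class:`GenomeSet` — several named
genomes, each holding gene records with both the coding sequence and its
translation.  Records optionally carry a ``family_id`` ground-truth tag
(set by the simulator) which downstream code treats as opaque metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .codonalign import translate


@dataclass
class GeneRecord:
    gene_id: str
    cds: str
    protein: str
    family_id: str | None = None

    @classmethod
    def from_cds(cls, gene_id: str, cds: str, family_id: str | None = None) -> "GeneRecord":
        return cls(gene_id=gene_id, cds=cds, protein=translate(cds), family_id=family_id)


@dataclass
class Genome:
    genome_id: str
    genes: dict[str, GeneRecord] = field(default_factory=dict)

    def add(self, record: GeneRecord) -> None:
        if record.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {record.gene_id!r} in {self.genome_id!r}")
        self.genes[record.gene_id] = record

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenomeSet:
    genomes: dict[str, Genome] = field(default_factory=dict)

    def add(self, genome: Genome) -> None:
        if genome.genome_id in self.genomes:
            raise ValueError(f"duplicate genome id {genome.genome_id!r}")
        self.genomes[genome.genome_id] = genome

    def gene_to_genome(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g in self.genomes.values():
            for gid in g.genes:
                if gid in out:
                    raise ValueError(f"gene id {gid!r} appears in two genomes")
                out[gid] = g.genome_id
        return out

    def record(self, gene_id: str) -> GeneRecord:
        for g in self.genomes.values():
            if gene_id in g.genes:
                return g.genes[gene_id]
        raise KeyError(gene_id)

    def n_genes(self) -> int:
        return sum(len(g) for g in self.genomes.values())

    # -- persistence -----------------------------------------------------

    def write(self, out_dir: str | Path) -> dict:
        """Write per-genome protein/CDS FASTA plus a truth TSV and manifest.

        Returns the manifest dict (also written as ``manifest.json``).
        Layout: ``<genome>.pep.fasta`` / ``<genome>.cds.fasta`` per genome,
        ``truth.tsv`` with (genome_id, gene_id, family_id) rows for tagged
        genes.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        truth_rows = []
        for genome_id in sorted(self.genomes):
            genome = self.genomes[genome_id]
            pep = out / f"{genome_id}.pep.fasta"
            cds = out / f"{genome_id}.cds.fasta"
            with open(pep, "w") as fp, open(cds, "w") as fc:
                for gid in sorted(genome.genes):
                    rec = genome.genes[gid]
                    fp.write(f">{gid}\n{rec.protein}\n")
                    fc.write(f">{gid}\n{rec.cds}\n")
                    if rec.family_id is not None:
                        truth_rows.append((genome_id, gid, rec.family_id))
            files += [pep.name, cds.name]
        truth = out / "truth.tsv"
        with open(truth, "w") as fh:
            fh.write("genome_id\tgene_id\tfamily_id\n")
            for row in truth_rows:
                fh.write("\t".join(row) + "\n")
        manifest = {
            "genomes": sorted(self.genomes),
            "files": files + [truth.name],
            "n_genes": self.n_genes(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest

    @classmethod
    def read(cls, in_dir: str | Path) -> "GenomeSet":
        """Read a directory of ``<genome>.pep.fasta``/``<genome>.cds.fasta``.

        The truth TSV, if present, restores ``family_id`` tags.
        """
        in_dir = Path(in_dir)
        truth: dict[str, str] = {}
        tpath = in_dir / "truth.tsv"
        if tpath.exists():
            with open(tpath) as fh:
                next(fh)
                for line in fh:
                    genome_id, gene_id, family_id = line.rstrip("\n").split("\t")
                    truth[gene_id] = family_id
        gs = cls()
        for cds_path in sorted(in_dir.glob("*.cds.fasta")):
            genome_id = cds_path.name[: -len(".cds.fasta")]
            pep_path = in_dir / f"{genome_id}.pep.fasta"
            proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(pep_path), "fasta")}
            genome = Genome(genome_id)
            for rec in SeqIO.parse(str(cds_path), "fasta"):
                genome.add(
                    GeneRecord(
                        gene_id=rec.id,
                        cds=str(rec.seq),
                        protein=proteins[rec.id],
                        family_id=truth.get(rec.id),
                    )
                )
            gs.add(genome)
        return gs
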