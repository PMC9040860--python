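"""Real-data mode: analyses on deposited M. smegmatis genome accessions.

The parental genomes of the five-strain panel are deposited at NCBI
(MKD8 CP027541.1, Jucho CP080274, Rabinowitchi CP080272, Nishi CP080273,
mc2-155 NC_008596). These helpers run the locus-level analyses on local
FASTA copies of those accessions; downloading is left to the user (e.g.
``efetch``/``datasets``), since the analyses themselves are offline.

Expected layout under ``data_dir``::

    <accession>.fasta                 # full genome, one record
    esx1_loci.json                    # {accession: [start, end]} 0-based
    esx1_proteins_<accession>.faa     # esx1-encoded proteins, ids shared
                                      # between strains for ortholog pairing
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .io import read_genome
from .locus import ProteinPair, locus_snv_report, min_core_identity, LocusSNV

# Accessions of the deposited parental genomes, by strain.
STRAIN_ACCESSIONS = {
    "MKD8": "CP027541.1",
    "Jucho": "CP080274",
    "Rabinowitchi": "CP080272",
    "Nishi": "CP080273",
    "mc2-155": "NC_008596",
}

# The polymorphic mid genes and the IS cluster originally mapped with them;
# excluded from "core" esx1 conservation screens.
MID_REGION_GENES = tuple(f"Msmeg{n:04d}" for n in range(69, 79))


class AccessionDataMissing(FileNotFoundError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise AccessionDataMissing(
            f"{path} not found — download the accession FASTA from NCBI and "
            f"place it there (see dctmosaic.accessions docstring for layout)"
        )
    return path


def genome_length(data_dir: str | Path, accession: str) -> int:
    """Parsed length in bp of a locally stored accession FASTA."""
    genome = read_genome(_require(Path(data_dir) / f"{accession}.fasta"))
    return genome.length_bp


def extract_locus(data_dir: str | Path, accession: str) -> str:
    """The esx1 locus sequence of an accession, per ``esx1_loci.json``."""
    data_dir = Path(data_dir)
    coords = json.loads(_require(data_dir / "esx1_loci.json").read_text())
    if accession not in coords:
        raise AccessionDataMissing(
            f"esx1_loci.json has no coordinates for {accession}"
        )
    start, end = coords[accession]
    genome = read_genome(_require(data_dir / f"{accession}.fasta"))
    return genome.sequence[start:end]


def esx1_locus_snvs(
    data_dir: str | Path, accession_a: str, accession_b: str
) -> list[LocusSNV]:
    """Substitutions between the esx1 loci of two stored accessions."""
    locus_a = extract_locus(data_dir, accession_a)
    locus_b = extract_locus(data_dir, accession_b)
    return locus_snv_report(locus_a, locus_b)


def core_ortholog_min_identity(
    data_dir: str | Path,
    accession_a: str,
    accession_b: str,
    exclude: Sequence[str] = MID_REGION_GENES,
) -> tuple[float, str]:
    """Minimum global amino-acid identity over shared esx1 ortholog pairs.

    Proteins are paired by identical record ids between the two per-strain
    FASTA files; ids listed in ``exclude`` (default: the polymorphic mid
    region, Msmeg0069–0078) are skipped.
    """
    from Bio import SeqIO

    data_dir = Path(data_dir)
    recs_a = {
        r.id: str(r.seq)
        for r in SeqIO.parse(
            _require(data_dir / f"esx1_proteins_{accession_a}.faa"), "fasta"
        )
    }
    recs_b = {
        r.id: str(r.seq)
        for r in SeqIO.parse(
            _require(data_dir / f"esx1_proteins_{accession_b}.faa"), "fasta"
        )
    }
    shared = sorted(set(recs_a) & set(recs_b))
    if not shared:
        raise AccessionDataMissing(
            "no shared protein ids between the two esx1 protein files"
        )
    pairs = [ProteinPair(i, i, recs_a[i], recs_b[i]) for i in shared]
    return min_core_identity(pairs, exclude=exclude)
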