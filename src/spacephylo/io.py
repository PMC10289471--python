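"""Readers and writers for the package's text formats.

Conventions: Newick branch lengths are generations and always written;
tip labels are ``species_individual_homolog``. Alignments are A/T coded
(A ancestral, 0; T derived, 1). The VCF dialect is a minimal VCFv4.2 with
phased GT fields, one diploid sample per individual; reading haploidises
genotypes back into per-homolog haplotypes. Coordinates are continuous
with the origin at the habitat's lower-left corner; site indices are
0-based internally and 1-based in VCF POS. Every writer round-trips with
the matching reader.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genealogy import GeneTree, VariantTable

__all__ = [
    "write_newick_trees",
    "read_newick_trees",
    "write_fasta",
    "read_fasta",
    "write_nexus",
    "read_nexus",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_vcf",
    "read_vcf",
    "write_sample_table",
    "read_sample_table",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


# -- trees -------------------------------------------------------------------


def write_newick_trees(trees, path) -> None:
    """One Newick string per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def read_newick_trees(path, tip_meta: pd.DataFrame | None = None):
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if line:
                trees.append(
                    GeneTree.from_newick(line, locus=i, tip_meta=tip_meta)
                )
    return trees


# -- alignments --------------------------------------------------------------


def write_fasta(alignment: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = ""
            else:
                out[name] += line
    return out


def write_nexus(alignment: dict[str, str], path, datatype: str = "dna") -> None:
    """Minimal NEXUS DATA block (single alignment)."""
    names = list(alignment)
    nchar = len(next(iter(alignment.values())))
    width = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(names)} NCHAR={nchar};\n")
        fh.write(
            f"  FORMAT DATATYPE={datatype.upper()} MISSING=? GAP=-;\n"
        )
        fh.write("  MATRIX\n")
        for n in names:
            fh.write(f"    {n:<{width}}{alignment[n]}\n")
        fh.write("  ;\nEND;\n")


def read_nexus(path) -> dict[str, str]:
    out: dict[str, str] = {}
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if s == ";" or s.upper().startswith("END"):
                    break
                if s:
                    name, seq = s.split(None, 1)
                    out[name] = out.get(name, "") + seq.replace(" ", "")
    return out


# -- variants ----------------------------------------------------------------


def write_variants_tsv(variants: VariantTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##haplotypes=" + ",".join(variants.haplotypes) + "\n")
        if variants.locus_length is not None:
            fh.write(f"##locus_length={variants.locus_length}\n")
        fh.write("locus\tsite\tancestral\tderived\tcarriers\n")
        for l, s, c in zip(variants.locus, variants.site, variants.carriers):
            fh.write(f"{l}\t{s}\t0\t1\t{','.join(sorted(c))}\n")


def read_variants_tsv(path) -> VariantTable:
    haps: list[str] = []
    locus_length = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##haplotypes="):
                haps = line.split("=", 1)[1].split(",")
                continue
            if line.startswith("##locus_length="):
                locus_length = int(line.split("=", 1)[1])
                continue
            if line.startswith("locus\t") or not line:
                continue
            parts = line.split("\t")
            carriers = frozenset(
                parts[4].split(",") if len(parts) > 4 and parts[4] else []
            )
            rows.append((int(parts[0]), int(parts[1]), carriers))
    return VariantTable(
        haplotypes=haps,
        locus=np.array([r[0] for r in rows], dtype=np.int64),
        site=np.array([r[1] for r in rows], dtype=np.int64),
        carriers=[r[2] for r in rows],
        locus_length=locus_length,
    )


def _diploid_samples(haplotypes: list[str]):
    """Group per-homolog labels ``name_0``/``name_1`` into diploid samples."""
    bases: dict[str, list] = {}
    for h in haplotypes:
        if h.endswith(("_0", "_1")):
            base, hom = h.rsplit("_", 1)
            bases.setdefault(base, [None, None])[int(hom)] = h
    diploid = {
        b: pair for b, pair in bases.items() if None not in pair
    }
    if len(diploid) * 2 == len(haplotypes):
        return diploid
    return None


def write_vcf(variants: VariantTable, path) -> None:
    """Minimal VCF: phased diploid GT columns (REF=A ancestral, ALT=T)."""
    diploid = _diploid_samples(variants.haplotypes)
    if diploid is None:
        samples = {h: (h,) for h in variants.haplotypes}
    else:
        samples = {b: tuple(p) for b, p in diploid.items()}
    names = list(samples)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=.,Number=0,Type=Flag,Description="none">\n')
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for l, s, carr in zip(
            variants.locus, variants.site, variants.carriers
        ):
            gts = []
            for n in names:
                alleles = ["1" if h in carr else "0" for h in samples[n]]
                gts.append("|".join(alleles))
            fh.write(
                f"locus{l}\t{s + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> VariantTable:
    """Read the minimal VCF back, haploidising GT fields."""
    rows = []
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                names = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos = parts[0], int(parts[1])
            locus = int(chrom.replace("locus", "")) if chrom.startswith(
                "locus"
            ) else 0
            gts = parts[9:]
            rows.append((locus, pos - 1, gts))
    haplotypes: list[str] = []
    ploidies: list[int] = []
    if rows:
        for name, gt in zip(names, rows[0][2]):
            alleles = gt.replace("/", "|").split("|")
            ploidies.append(len(alleles))
            if len(alleles) == 1:
                haplotypes.append(name)
            else:
                haplotypes.extend(f"{name}_{i}" for i in range(len(alleles)))
    carriers = []
    for _, _, gts in rows:
        carr = set()
        hi = 0
        for gt, p in zip(gts, ploidies):
            alleles = gt.replace("/", "|").split("|")
            for a in alleles:
                if a == "1":
                    carr.add(haplotypes[hi])
                hi += 1
        carriers.append(frozenset(carr))
    return VariantTable(
        haplotypes=haplotypes,
        locus=np.array([r[0] for r in rows], dtype=np.int64),
        site=np.array([r[1] for r in rows], dtype=np.int64),
        carriers=carriers,
    )


# -- tables ------------------------------------------------------------------


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix_tsv(matrix: np.ndarray, path, labels=None) -> None:
    df = pd.DataFrame(np.asarray(matrix))
    if labels is not None:
        df.index = df.columns = list(labels)
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
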