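"""Shared fixtures: tiny hand-written input files and a brute-force scorer.

The brute-force scorer is an independent nested-loop oracle for the
variant → gene → drug score hierarchy; it deliberately avoids the
vectorised log-space path of the package so the two can be compared.
"""

import math

import numpy as np
import pytest

from pharmscore.io import (
    AnnotationSet,
    DrugGeneMap,
    GenotypeCarriage,
    VariantAnnotation,
    VariantKey,
)


def brute_force_scores(carriage, annotations, drug_map, epsilon=0.001):
    """Nested-loop reference implementation of per-individual D scores."""
    col_of = {k: j for j, k in enumerate(carriage.variants)}
    # gene -> {variant key: clamped V}, duplicates once
    by_gene = {}
    for a in annotations:
        if a.key in col_of:
            by_gene.setdefault(a.gene, {})[a.key] = max(a.sift, epsilon)
    out = {}
    for i, ind in enumerate(carriage.individuals):
        for drug in sorted(drug_map.entries):
            g_scores = []
            for gene in sorted(drug_map.entries[drug]):
                vs = [
                    v for key, v in by_gene.get(gene, {}).items()
                    if carriage.carriage[i, col_of[key]]
                ]
                if vs:
                    prod = 1.0
                    for v in vs:
                        prod *= v
                    g_scores.append(prod ** (1.0 / len(vs)))
                else:
                    g_scores.append(1.0)
            prod = 1.0
            for g in g_scores:
                prod *= g
            out[(ind, drug)] = prod ** (1.0 / len(g_scores))
    return out


def make_annotation(chrom, pos, gene, sift, ref="A", alt="G"):
    return VariantAnnotation(
        key=VariantKey(str(chrom), int(pos), ref, alt),
        gene=gene,
        consequence="nonsynonymous",
        sift=float(sift),
    )


def random_tiny_inputs(rng, n_ind=None, n_drugs=None):
    """A random cohort of <= 10 individuals x <= 4 drugs for oracle checks."""
    n_ind = n_ind or int(rng.integers(2, 11))
    n_genes = int(rng.integers(3, 9))
    n_drugs = n_drugs or int(rng.integers(1, 5))
    genes = [f"g{k}" for k in range(n_genes)]
    records = []
    pos = 1
    for g in genes:
        for _ in range(int(rng.integers(0, 4))):
            records.append(make_annotation("1", pos, g, float(rng.random())))
            pos += 1
    annotations = AnnotationSet(records, n_input=len(records), n_dropped=0)
    carriage = GenotypeCarriage(
        individuals=[f"i{i}" for i in range(n_ind)],
        variants=[r.key for r in records],
        carriage=rng.random((n_ind, len(records))) < 0.4,
    )
    entries = {}
    for m in range(n_drugs):
        size = int(rng.integers(1, n_genes + 1))
        picked = rng.choice(n_genes, size=size, replace=False)
        entries[f"d{m}"] = frozenset(genes[j] for j in picked)
    dmap = DrugGeneMap(entries=entries, min_genes=1)
    return carriage, annotations, dmap


@pytest.fixture
def toy_vcf(tmp_path):
    """3 samples, 4 records incl. one multi-allelic and one missing genotype."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
1\t200\t.\tC\tA,T\t.\tPASS\t.\tGT\t1/1\t0/2\t0/0
1\t300\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
2\t50\t.\tT\tC\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def toy_annotations_tsv(tmp_path):
    text = (
        "# toy annotation table\n"
        "chrom\tpos\tref\talt\tgene\tconsequence\tsift\n"
        "1\t100\tA\tG\tGENEA\tnonsynonymous\t0.2\n"
        "1\t200\tC\tA\tGENEA\tnonsynonymous\t0.05\n"
        "1\t200\tC\tT\tGENEB\tnonsynonymous\t0.5\n"
        "1\t300\tG\tC\tGENEB\tnonsynonymous\t0.9\n"
        "2\t50\tT\tC\tGENEC\tnonsynonymous\t0.0\n"
        "3\t10\tA\tC\tGENED\tsynonymous\t0.4\n"
    )
    path = tmp_path / "annotations.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def toy_drug_genes_tsv(tmp_path):
    rows = ["drug_id\tgene\trole"]
    # drugX: 5 genes (included at default threshold), drugY: 2 genes
    for g in ["GENEA", "GENEB", "GENEC", "GENED", "GENEE"]:
        rows.append(f"drugX\t{g}\ttarget")
    rows.append("drugY\tGENEA\tenzyme")
    rows.append("drugY\tGENEB\t")
    path = tmp_path / "drug_genes.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def toy_status_tsv(tmp_path):
    text = (
        "drug_id\twithdrawn_UN\twithdrawn_EMA\twithdrawn_DrugBank\t"
        "precaution_Beers\tprecaution_FDA\n"
        "drugX\t1\t0\t0\t1\t0\n"
        "drugY\t0\t0\t0\t0\t0\n"
    )
    path = tmp_path / "status.tsv"
    path.write_text(text)
    return path
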