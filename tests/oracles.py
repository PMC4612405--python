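"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive the transmitting-gene criteria by exhaustive
enumeration (including the literal read-pair search for criterion c) so they
share no code path with the package's detector.
"""

from collections import defaultdict

from graftmrna.alignio import Alignment
from graftmrna.genotyping import DiagnosticSNP
from graftmrna.mobility import CONFLICTED, DONOR, RECEPTOR, UNINFORMATIVE, ClassifiedRead

LABELS = (DONOR, RECEPTOR, UNINFORMATIVE, CONFLICTED)


def brute_force_transmitting(classified):
    """Exhaustive criteria check; returns {gene_id: set of criteria}.

    Unique reads are distinct (contig, start, strand) coordinates; loci of
    reads sharing coordinates are pooled, as duplicates of one molecule.
    """
    per_gene: dict[str, dict[tuple, set[int]]] = defaultdict(lambda: defaultdict(set))
    for cr in classified:
        if cr.label != DONOR:
            continue
        for snp, _ in cr.covered:
            if snp.gene_id:
                per_gene[snp.gene_id][cr.unique_key].add(snp.position)

    verdicts = {}
    for gene, reads in per_gene.items():
        crit = set()
        keys = sorted(reads)
        for k in keys:
            if len(reads[k]) >= 2:
                crit.add("a")
        for locus in {p for loci in reads.values() for p in loci}:
            if sum(1 for k in keys if locus in reads[k]) >= 2:
                crit.add("b")
        # literal pair enumeration for criterion c
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1:]:
                if any(l1 != l2 for l1 in reads[k1] for l2 in reads[k2]):
                    crit.add("c")
        if crit:
            verdicts[gene] = crit
    return verdicts


def random_micro_instance(rng, max_reads=50, max_loci=10):
    """A random small classified-read instance over up to 3 genes."""
    n_loci = int(rng.integers(1, max_loci + 1))
    n_genes = int(rng.integers(1, 4))
    positions = sorted(rng.choice(range(10, 1000), size=n_loci, replace=False).tolist())
    snps = []
    for p in positions:
        gene = f"g{int(rng.integers(0, n_genes + 1))}"  # gene "g<n_genes>" never exists
        gene_id = gene if gene != f"g{n_genes}" else None  # some intergenic loci
        snps.append(DiagnosticSNP("chr1", int(p), "A", "A", "B", "G", gene_id=gene_id))
    n_reads = int(rng.integers(0, max_reads + 1))
    classified = []
    for i in range(n_reads):
        start = int(rng.integers(1, 30))  # narrow range: coordinate collisions happen
        strand = "+-"[int(rng.integers(2))]
        label = LABELS[int(rng.choice([0, 0, 0, 1, 2, 3]))]  # donor-heavy mix
        k = int(rng.integers(1, min(4, n_loci) + 1))
        chosen = rng.choice(len(snps), size=k, replace=False)
        covered = tuple((snps[j], snps[j].allele_of("B")) for j in sorted(chosen))
        aln = Alignment(read_id=f"r{i}", library="L", contig="chr1", start=start,
                        strand=strand, seq="A", mismatches=())
        classified.append(ClassifiedRead(aln, covered, label, label == DONOR))
    return snps, classified
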