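"""Independent brute-force reimplementations of the per-plot indices,
written as plain tallies so they share no code path with the package."""

from __future__ import annotations


def plot_genotypes(table, plot_id):
    """[(locus -> (a, b)), ...] for the plot's samples."""
    return [s.alleles for s in table.samples if s.plot_id == plot_id]


def locus_tally(genos, locus):
    counts: dict[int, int] = {}
    n = 0
    for g in genos:
        a, b = g[locus]
        if a is None or b is None:
            continue
        n += 1
        for v in (a, b):
            counts[v] = counts.get(v, 0) + 1
    return counts, n


def brute_na(table, plot_id):
    genos = plot_genotypes(table, plot_id)
    per_locus = []
    for locus in table.loci:
        counts, n = locus_tally(genos, locus)
        if n > 0:
            per_locus.append(len(counts))
    return sum(per_locus) / len(per_locus)


def brute_ne(table, plot_id):
    genos = plot_genotypes(table, plot_id)
    per_locus = []
    for locus in table.loci:
        counts, n = locus_tally(genos, locus)
        if n == 0:
            continue
        total = 2 * n
        sum_p2 = sum((c / total) ** 2 for c in counts.values())
        per_locus.append(1 / sum_p2)
    return sum(per_locus) / len(per_locus)


def brute_ho(table, plot_id):
    genos = plot_genotypes(table, plot_id)
    per_locus = []
    for locus in table.loci:
        n = het = 0
        for g in genos:
            a, b = g[locus]
            if a is None or b is None:
                continue
            n += 1
            het += a != b
        if n > 0:
            per_locus.append(het / n)
    return sum(per_locus) / len(per_locus)


def brute_uhe(table, plot_id):
    genos = plot_genotypes(table, plot_id)
    per_locus = []
    for locus in table.loci:
        counts, n = locus_tally(genos, locus)
        if n == 0:
            continue
        total = 2 * n
        sum_p2 = sum((c / total) ** 2 for c in counts.values())
        per_locus.append(total / (total - 1) * (1 - sum_p2))
    return sum(per_locus) / len(per_locus)


def brute_f(table, plot_id):
    genos = plot_genotypes(table, plot_id)
    per_locus = []
    for locus in table.loci:
        counts, n = locus_tally(genos, locus)
        if n == 0:
            continue
        total = 2 * n
        he = 1 - sum((c / total) ** 2 for c in counts.values())
        if he <= 0:
            continue
        het = 0
        for g in genos:
            a, b = g[locus]
            if a is not None and b is not None and a != b:
                het += 1
        ho = het / n
        per_locus.append((he - ho) / he)
    if not per_locus:
        return None
    return sum(per_locus) / len(per_locus)


def brute_mlg_count(table):
    """Number of distinct complete multilocus genotypes, by pairwise
    signature comparison."""
    sigs = []
    for s in table.samples:
        if any(v is None for p in s.alleles.values() for v in p):
            continue
        sig = tuple(tuple(sorted(s.alleles[l])) for l in table.loci)
        sigs.append(sig)
    distinct = []
    for sig in sigs:
        if not any(sig == d for d in distinct):
            distinct.append(sig)
    return len(distinct)
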