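"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the glycomodule
oracle uses regex site enumeration plus O(n^2) all-pairs clustering, and
the NG86 oracle uses Biopython translation with recursive pathway
enumeration.
"""

import itertools
import re

from Bio.Seq import Seq

MAX_SITE_GAP = 10


def glyco_oracle_sites(seq):
    """[A/S/T]P sites as (1-based position, full P-run length)."""
    out = []
    for m in re.finditer(r"(?=[AST]P)", seq):
        pos = m.start() + 1
        run = len(re.match(r"P+", seq[pos:]).group(0))
        out.append((pos, run))
    return out


def glyco_oracle_modules(seq, excluded=()):
    """Qualifying modules as sorted (start, end, n_sites) triples."""
    sites = [
        (p, r)
        for p, r in glyco_oracle_sites(seq)
        if not any(p <= xe and xs <= p + r for xs, xe in excluded)
    ]
    n = len(sites)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lo, hi = sorted([sites[i], sites[j]])
            gap = hi[0] - (lo[0] + lo[1]) - 1
            if gap <= MAX_SITE_GAP:
                parent[find(i)] = find(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(sites[i])
    modules = []
    for members in clusters.values():
        members.sort()
        if len(members) >= 2 or members[0][1] >= 2:
            modules.append(
                (members[0][0], members[-1][0] + members[-1][1], len(members))
            )
    return sorted(modules)


def _aa(codon):
    return str(Seq(codon).translate())


def ng86_oracle_pair(ca, cb):
    """(S, N, Sd, Nd) for an aligned codon pair by exhaustive enumeration."""
    S = 0.0
    for codon in (ca, cb):
        for pos in range(3):
            syn = tot = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if _aa(mut) == "*":
                    continue
                tot += 1
                syn += _aa(mut) == _aa(codon)
            if tot:
                S += syn / tot / 2  # averaged over the two codons
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return S, 3.0 - S, 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            path_counts.append((sd, nd))
    if not path_counts:  # every pathway hits a stop: keep them all
        for order in itertools.permutations(diff):
            cur, sd, nd = ca, 0, 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _aa(nxt) != "*" and _aa(cur) != "*" and _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            path_counts.append((sd, nd))
    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return S, 3.0 - S, sd, nd
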