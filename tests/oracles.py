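"""Independent brute-force reference implementations.

Each oracle recomputes an operation from its definition with the most
naive strategy available (explicit loops, regex scans, exhaustive
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import re

import numpy as np

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
STOPS = {"TAA", "TAG", "TGA"}


def greedy_species_clusters(
    ids: list[str],
    lengths: dict[str, int],
    ani: dict[tuple[str, str], float],
    af: dict[tuple[str, str], float],
    min_ani: float = 95.0,
    min_af: float = 85.0,
) -> list[tuple[str, frozenset]]:
    """Greedy centroid clustering straight from the rule statement."""
    order = sorted(ids, key=lambda g: (-lengths[g], g))
    reps: list[str] = []
    members: dict[str, set[str]] = {}
    for g in order:
        placed = False
        for rep in reps:
            key = (rep, g) if (rep, g) in ani else (g, rep)
            if ani[key] >= min_ani and af[key] > min_af:
                members[rep].add(g)
                placed = True
                break
        if not placed:
            reps.append(g)
            members[g] = {g}
    return [(r, frozenset(members[r])) for r in reps]


def tpmean_naive(depths: list[int], trim: float = 0.10) -> float:
    d = sorted(depths)
    L = len(d)
    if L < 10:
        return sum(d) / L
    k = int(np.floor(trim * L))
    kept = d[k : L - k] if k else d
    return sum(kept) / len(kept)


def filter_alignments_naive(rows, min_qf, min_id):
    out = []
    for r in rows:
        if r.aligned_len / r.query_len >= min_qf and r.matches / r.aligned_len >= min_id:
            out.append(r)
    return out


def depth_profile_naive(intervals: list[tuple[int, int]], target_len: int) -> list[int]:
    depth = [0] * target_len
    for start, end in intervals:
        for pos in range(start, end):
            depth[pos] += 1
    return depth


def rank_walk_naive(lineages, aai_stats, ranks, majority=0.70,
                    gates={"family": (2, 30.0), "genus": (3, 40.0)}):
    """Exhaustive majority-rule walk from species up."""
    n = len(lineages)
    if n == 0:
        return None, 0.0
    for depth in range(len(ranks) - 1, -1, -1):
        tally = {}
        for lin in lineages:
            if lin[depth]:
                tally[lin[depth]] = tally.get(lin[depth], 0) + 1
        if not tally:
            continue
        best_taxon = max(tally, key=lambda t: (tally[t], t))
        if tally[best_taxon] / n <= majority:
            continue
        rank = ranks[depth]
        if rank in gates:
            need_n, need_aai = gates[rank]
            if not any(np_ >= need_n and aai > need_aai for np_, aai in aai_stats.values()):
                continue
        return (ranks[depth], best_taxon), tally[best_taxon] / n
    return None, 0.0


def mcl_naive(nodes, edges, inflation, tol=1e-9, max_iter=200, prune=1e-12):
    """Pure-python Markov clustering, matching the stated iteration."""
    nodes = sorted(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mat = [[0.0] * n for _ in range(n)]
    for u, v, w in edges:
        mat[idx[u]][idx[v]] = w
        mat[idx[v]][idx[u]] = w
    for i in range(n):
        incident = max(mat[i]) if any(mat[i]) else 1.0
        mat[i][i] = incident
    # column normalize
    def normalize(m):
        for j in range(n):
            s = sum(m[i][j] for i in range(n)) or 1.0
            for i in range(n):
                m[i][j] /= s
        return m

    mat = normalize(mat)
    for _ in range(max_iter):
        sq = [[sum(mat[i][k] * mat[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        infl = [[(sq[i][j] ** inflation if sq[i][j] >= prune else 0.0)
                 for j in range(n)] for i in range(n)]
        infl = normalize(infl)
        delta = max(abs(infl[i][j] - mat[i][j]) for i in range(n) for j in range(n))
        mat = infl
        if delta < tol:
            break
    # connected components of the support
    adj = {v: set() for v in nodes}
    for i in range(n):
        for j in range(n):
            if i != j and mat[i][j] > prune:
                adj[nodes[i]].add(nodes[j])
                adj[nodes[j]].add(nodes[i])
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return sorted(comps, key=min)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def orfs_naive(seq: str, min_aa: int = 60):
    """Regex-style six-frame enumeration of first-ATG-to-stop ORFs."""
    L = len(seq)
    found = set()
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, L - 2, 3)]
            start = None
            for ci, codon in enumerate(codons):
                if codon == "ATG" and start is None:
                    start = ci
                elif codon in STOPS:
                    if start is not None and ci - start >= min_aa:
                        nt0 = frame + 3 * start
                        nt1 = frame + 3 * ci + 3
                        if strand == "-":
                            nt0, nt1 = L - nt1, L - nt0
                        prot = "".join(
                            CODON_TABLE[c] for c in codons[start:ci]
                        )
                        found.add((nt0, nt1, strand, prot))
                    start = None
    return found
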