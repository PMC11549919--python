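"""Virus-host link prediction by three complementary methods.

1. CRISPR spacers: arrays of >= 3 exact repeat copies are detected in
   host genomes and their spacers matched full-length, gapless, with at
   most one substitution against both strands of each virus.
2. Shared genomic regions: prophage-style matches of >= 1000 bp at
   >= 90% identity found with the seed-chain-extend engine.
3. k-mer signatures: an order-k Markov model per host scores each
   virus; significance comes from a Gaussian fit to the scores of
   dinucleotide-preserving shuffles of the virus, and the host with
   the lowest p-value is retained when p <= 1e-5.

The union of the three methods, de-duplicated per (virus, host) pair
with supporting methods listed, is the link set used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .io_formats import GenomeRecord, revcomp
from .seqalign import local_matches

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class CrisprArray:
    host_id: str
    repeat_seq: str
    # (spacer sequence, start, end) in host coordinates
    spacers: tuple[tuple[str, int, int], ...]
    start: int
    end: int


@dataclass(frozen=True)
class HostLink:
    """A predicted (virus, host) pair with its supporting evidence.

    ``methods`` lists every method that proposed the pair; per-method
    evidence payloads live in ``evidence`` keyed by method name.
    """

    virus_id: str
    host_id: str
    methods: tuple[str, ...]
    evidence: dict = field(default_factory=dict, compare=False)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.virus_id, self.host_id)


@dataclass
class MarkovModel:
    """Order-k host composition model with pseudocount-1 smoothing."""

    host_id: str
    k: int
    log_transition: np.ndarray  # (4^k, 4) log-probabilities

    def __post_init__(self) -> None:
        probs = np.exp(self.log_transition)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("per-context probabilities must sum to 1")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for base, i in _BASE_IDX.items():
        out[arr == ord(base)] = i
    return out


def find_crispr_arrays(
    genome: GenomeRecord,
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (20, 72),
) -> list[CrisprArray]:
    """Detect arrays of exact repeat copies separated by spacers.

    Seeds are k-mers of the minimum repeat length occurring >=
    ``min_repeats`` times at spacings compatible with the spacer-length
    window; the full repeat is the maximal common forward extension of
    all copies.  Overlapping candidates are resolved leftmost-first.
    """
    if len(genome.seq) < 200:
        raise ValueError("genome too short for CRISPR detection")
    seq = genome.seq
    k0 = repeat_len[0]
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k0 + 1):
        index.setdefault(seq[i : i + k0], []).append(i)
    min_gap = k0 + spacer_len[0]
    max_gap = repeat_len[1] + spacer_len[1]
    candidates: list[tuple[int, list[int]]] = []
    for positions in index.values():
        if len(positions) < min_repeats:
            continue
        run = [positions[0]]
        for p in positions[1:]:
            gap = p - run[-1]
            if min_gap <= gap <= max_gap:
                run.append(p)
            else:
                if len(run) >= min_repeats:
                    candidates.append((run[0], run))
                run = [p]
        if len(run) >= min_repeats:
            candidates.append((run[0], run))
    arrays: list[CrisprArray] = []
    taken_until = -1
    for start, run in sorted(candidates):
        if start <= taken_until:
            continue
        # extend the repeat while all copies agree, bounded by the
        # repeat-length cap and the minimum spacer length
        min_run_gap = min(b - a for a, b in zip(run, run[1:]))
        cap = min(repeat_len[1], min_run_gap - spacer_len[0])
        r = k0
        while r < cap:
            nxt = {seq[p + r] if p + r < len(seq) else None for p in run}
            if len(nxt) != 1 or None in nxt:
                break
            r += 1
        spacer_records = []
        ok = True
        for a, b in zip(run, run[1:]):
            s_start, s_end = a + r, b
            slen = s_end - s_start
            if not spacer_len[0] <= slen <= spacer_len[1]:
                ok = False
                break
            spacer_records.append((seq[s_start:s_end], s_start, s_end))
        if not ok:
            continue
        end = run[-1] + r
        arrays.append(
            CrisprArray(genome.id, seq[run[0] : run[0] + r], tuple(spacer_records),
                        run[0], end)
        )
        taken_until = end
    return arrays


def match_spacers(
    arrays: Sequence[CrisprArray],
    viruses: Sequence[GenomeRecord],
    max_mismatch: int = 1,
) -> list[HostLink]:
    """Full-length, gapless spacer matching against both virus strands.

    A link is emitted when any spacer matches with <= ``max_mismatch``
    substitutions; evidence records the best (fewest-mismatch) spacer
    hit and exact (0-mismatch) links are flagged.
    """
    links: dict[tuple[str, str], dict] = {}
    encoded = {
        v.id: (_encode(v.seq), _encode(revcomp(v.seq))) for v in viruses
    }
    for array in arrays:
        for spacer, _, _ in array.spacers:
            pat = _encode(spacer)
            L = len(pat)
            for v in viruses:
                best = None
                for strand_arr in encoded[v.id]:
                    if len(strand_arr) < L:
                        continue
                    windows = sliding_window_view(strand_arr, L)
                    mism = (windows != pat).sum(axis=1)
                    m = int(mism.min())
                    if best is None or m < best:
                        best = m
                if best is not None and best <= max_mismatch:
                    key = (v.id, array.host_id)
                    prev = links.get(key)
                    if prev is None or best < prev["mismatches"]:
                        links[key] = {
                            "mismatches": best,
                            "exact": best == 0,
                            "spacer": spacer,
                        }
    return [
        HostLink(v, h, ("spacer",), {"spacer": ev}) for (v, h), ev in sorted(links.items())
    ]


def find_shared_regions(
    virus: GenomeRecord,
    host: GenomeRecord,
    min_len: int = 1000,
    min_identity: float = 0.90,
) -> list[HostLink]:
    """Prophage-style shared-region links via seed-chain-extend matching.

    Matches of >= ``min_len`` aligned columns at >= ``min_identity``
    become links; at those thresholds a BLAST E-value would be
    vanishingly small, so no separate significance cut is applied.
    """
    if len(virus.seq) < min_len or len(host.seq) < min_len:
        return []
    blocks = local_matches(virus.seq, host.seq, min_columns=min_len)
    hits = [
        b for b in blocks if b.columns >= min_len and b.identity >= min_identity
    ]
    if not hits:
        return []
    best = max(hits, key=lambda b: b.columns)
    return [
        HostLink(
            virus.id,
            host.id,
            ("shared_region",),
            {
                "shared_region": {
                    "length": best.columns,
                    "identity": best.identity,
                    "n_blocks": len(hits),
                }
            },
        )
    ]


def train_markov(host: GenomeRecord, k: int = 3) -> MarkovModel:
    """Order-k transition counts over both strands, pseudocount 1."""
    if len(host.seq) < 100 * 4**k:
        raise ValueError(
            f"genome of length {len(host.seq)} too short for order {k}; "
            f"need >= {100 * 4 ** k} bp or a smaller k"
        )
    counts = np.ones((4**k, 4))
    for seq in (host.seq, revcomp(host.seq)):
        enc = _encode(seq)
        enc = enc[enc >= 0]
        if len(enc) <= k:
            continue
        ctx = np.zeros(len(enc) - k, dtype=np.int64)
        for i in range(k):
            ctx = ctx * 4 + enc[i : len(enc) - k + i]
        np.add.at(counts, (ctx, enc[k:]), 1)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return MarkovModel(host.id, k, np.log(probs))


def score_sequence(virus_seq: str, model: MarkovModel) -> float:
    """Mean per-base log-likelihood of the sequence under the model."""
    enc = _encode(virus_seq)
    enc = enc[enc >= 0]
    k = model.k
    if len(enc) <= k:
        raise ValueError("sequence shorter than model order")
    ctx = np.zeros(len(enc) - k, dtype=np.int64)
    for i in range(k):
        ctx = ctx * 4 + enc[i : len(enc) - k + i]
    return float(model.log_transition[ctx, enc[k:]].mean())


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # draw last-exit edges until they form an arborescence toward `last`
    for _ in range(10000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable for DNA
        raise RuntimeError("failed to sample an Eulerian shuffle")
    shuffled: dict[str, list[str]] = {}
    for v, out in edges.items():
        rest = list(out)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out_chars = [seq[0]]
    nexts = {v: iter(lst) for v, lst in shuffled.items()}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        cur = next(nexts[cur])
        out_chars.append(cur)
    return "".join(out_chars)


def predict_host(
    virus: GenomeRecord,
    models: Sequence[MarkovModel],
    n_null: int = 50,
    p_max: float = 1e-5,
    seed: int = 0,
) -> HostLink | None:
    """Best-host prediction with a shuffle-based Gaussian null.

    ``n_null`` dinucleotide-preserving shuffles of the virus are scored
    under each model; the observed score's upper-tail p-value under a
    Gaussian fit to the null scores is computed per host, and the host
    with the lowest p-value is returned when p <= ``p_max`` (ties break
    lexicographically by host id).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 host models")
    rng = np.random.default_rng(seed)
    shuffles = [dinucleotide_shuffle(virus.seq, rng) for _ in range(n_null)]
    best: tuple[float, str, dict] | None = None
    for model in sorted(models, key=lambda m: m.host_id):
        obs = score_sequence(virus.seq, model)
        null = np.array([score_sequence(s, model) for s in shuffles])
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            p = 1.0 if obs <= mu else 0.0
        else:
            p = float(stats.norm.sf(obs, loc=mu, scale=sd))
        if best is None or p < best[0]:
            best = (p, model.host_id, {"loglik": obs, "p_value": p})
    p, host_id, ev = best
    if p > p_max:
        return None
    return HostLink(virus.id, host_id, ("kmer",), {"kmer": ev})


def integrate_links(
    spacer_links: Sequence[HostLink],
    region_links: Sequence[HostLink],
    kmer_links: Sequence[HostLink],
) -> list[HostLink]:
    """Union of the three methods, de-duplicated per (virus, host) pair."""
    merged: dict[tuple[str, str], HostLink] = {}
    for link in [*spacer_links, *region_links, *kmer_links]:
        key = link.pair
        if key in merged:
            prev = merged[key]
            methods = tuple(sorted(set(prev.methods) | set(link.methods)))
            evidence = {**prev.evidence, **link.evidence}
            merged[key] = HostLink(link.virus_id, link.host_id, methods, evidence)
        else:
            merged[key] = link
    return [merged[k] for k in sorted(merged)]


def link_all(
    viruses: Sequence[GenomeRecord],
    hosts: Sequence[GenomeRecord],
    markov_order: int = 3,
    n_null: int = 50,
    p_max: float = 1e-5,
    seed: int = 0,
    provirus_coords: Mapping[str, tuple[str, int, int]] | None = None,
) -> list[HostLink]:
    """Run all three linking methods over a cohort and integrate.

    When ``provirus_coords`` flags a virus as a provirus, only the
    proviral subsequence (which is the viral genome itself here) is
    used — the flag exists for inputs where viral bins carry host
    flanks.
    """
    arrays = []
    for h in hosts:
        arrays.extend(find_crispr_arrays(h))
    spacer_links = match_spacers(arrays, viruses)
    region_links = []
    for v in viruses:
        for h in hosts:
            region_links.extend(find_shared_regions(v, h))
    models = [train_markov(h, markov_order) for h in hosts]
    rng = np.random.default_rng(seed)
    kmer_links = []
    for v in viruses:
        link = predict_host(
            v, models, n_null=n_null, p_max=p_max, seed=int(rng.integers(0, 2**31))
        )
        if link is not None:
            kmer_links.append(link)
    return integrate_links(spacer_links, region_links, kmer_links)
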