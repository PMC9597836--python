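"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles with
the slowest possible bookkeeping (path enumeration, per-window loops) so
they share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohbridge.pedigree import Pedigree, load_pedigree
from rohbridge.plinkio import GenotypeDataset, SnpMap
from rohbridge.roh import RohParams


# ---------------------------------------------------------------------------
# Wright path-counting inbreeding oracle

def _paths_up(parent_of: dict, start: str, target: str):
    """All ancestor paths from ``start`` up to ``target`` (node sequences)."""
    out = []

    def walk(node, path):
        if node == target:
            out.append(path)
            return
        for p in parent_of.get(node, ()):  # sire, dam
            if p is not None:
                walk(p, path + [p])

    walk(start, [start])
    return out


def wright_inbreeding(ped: Pedigree, animal_id: str, _memo=None) -> float:
    """F by enumerating non-overlapping ancestor-path pairs through every
    common ancestor: F = sum (1/2)^(n1+n2+1) * (1 + F_A)."""
    if _memo is None:
        _memo = {}
    if animal_id in _memo:
        return _memo[animal_id]
    sire, dam = ped.parents(animal_id)
    if sire is None or dam is None:
        _memo[animal_id] = 0.0
        return 0.0
    parent_of = {a: [r for r in ped.parents(a) if r is not None]
                 for a in ped.order}

    # all ancestors (incl. self) of each parent
    def anc(a):
        seen = {a}
        stack = [a]
        while stack:
            x = stack.pop()
            for p in parent_of.get(x, ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    common = anc(sire) & anc(dam)
    f = 0.0
    for a in common:
        fa = wright_inbreeding(ped, a, _memo)
        for p1 in _paths_up(parent_of, sire, a):
            for p2 in _paths_up(parent_of, dam, a):
                # paths may share only the common ancestor itself
                if set(p1) & set(p2) != {a}:
                    continue
                n1, n2 = len(p1) - 1, len(p2) - 1
                f += 0.5 ** (n1 + n2 + 1) * (1.0 + fa)
    _memo[animal_id] = f
    return f


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random valid pedigree: each animal may draw parents from predecessors."""
    rows = []
    for i in range(n):
        sire = dam = "0"
        if i >= 2 and rng.random() < 0.8:
            a, b = rng.choice(i, size=2, replace=False)
            sire, dam = f"A{a}", f"A{b}"
            if rng.random() < 0.15:
                sire = "0"
            if rng.random() < 0.15:
                dam = "0"
            if sire == dam:
                dam = "0"
        rows.append({"id": f"A{i}", "sire": sire, "dam": dam})
    return load_pedigree(rows)


# ---------------------------------------------------------------------------
# brute-force ROH oracle

def roh_oracle_one(genos: np.ndarray, pos: np.ndarray, params: RohParams):
    """Definition-based ROH scan for one individual on one chromosome.

    Enumerates every window explicitly, computes hit rates SNP by SNP,
    finds maximal eligible runs by linear scan, splits them at big gaps
    and applies each segment filter literally.  Returns a list of
    (start_bp, end_bp, n_snps) tuples.
    """
    n, w = len(genos), params.window_snps
    eligible = [False] * n
    if n >= w:
        hom = []
        for s in range(n - w + 1):
            win = genos[s:s + w]
            hom.append(
                int(np.sum(win == 1)) <= params.window_het_max
                and int(np.sum(win == -1)) <= params.window_missing_max
            )
        for i in range(n):
            covering = [hom[s] for s in range(max(0, i - w + 1),
                                              min(i, n - w) + 1)]
            eligible[i] = sum(covering) / len(covering) >= params.window_hit_threshold

    segments = []
    run: list[int] = []

    def flush(run):
        if not run:
            return
        # split at gaps
        pieces, piece = [], [run[0]]
        for a, b in zip(run, run[1:]):
            if pos[b] - pos[a] > params.max_gap_kb * 1000.0:
                pieces.append(piece)
                piece = []
            piece.append(b)
        pieces.append(piece)
        for pc in pieces:
            n_snps = len(pc)
            length = pos[pc[-1]] - pos[pc[0]] + 1
            if (n_snps >= params.min_snps
                    and length >= params.min_length_kb * 1000.0
                    and (length / 1000.0) / n_snps <= params.min_density_kb_per_snp):
                segments.append((int(pos[pc[0]]), int(pos[pc[-1]]), n_snps))

    for i in range(n):
        if eligible[i]:
            run.append(i)
        else:
            flush(run)
            run = []
    flush(run)
    return segments


def make_dataset(geno: np.ndarray, pos_by_chrom: dict[str, np.ndarray],
                 iids=None, species="sheep") -> GenotypeDataset:
    """Assemble a GenotypeDataset from a raw matrix and per-chrom positions."""
    rows = []
    for c, pos in pos_by_chrom.items():
        for j, p in enumerate(pos):
            rows.append((c, f"s{c}_{j}", 0.0, int(p), "A", "B"))
    snps = SnpMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "cm",
                                              "pos", "a1", "a2"]))
    n = geno.shape[0]
    iids = iids or [f"I{i}" for i in range(n)]
    samples = pd.DataFrame({"fid": ["0"] * n, "iid": iids,
                            "sire": "0", "dam": "0", "sex": "0", "pheno": "-9"})
    return GenotypeDataset(samples=samples, snps=snps, geno=geno,
                           species=species)


@pytest.fixture(scope="session")
def table2_models():
    """The published per-stratum fits used to exercise model selection."""
    from rohbridge.bridge import BridgeModel

    rows = [
        (0, 5085, 3028, 2057, 0.712, -0.028, 0.860, 0.507),
        (1, 4549, 2493, 2056, 0.725, -0.028, 0.888, 0.526),
        (2, 3911, 1877, 2034, 0.735, -0.027, 0.910, 0.540),
        (3, 3311, 1358, 1953, 0.753, -0.026, 0.937, 0.567),
        (4, 2522, 717, 1805, 0.782, -0.027, 0.971, 0.611),
        (5, 1602, 167, 1435, 0.825, -0.028, 1.010, 0.681),
        (6, 927, 18, 909, 0.849, -0.030, 1.056, 0.720),
        (7, 378, 2, 376, 0.847, -0.029, 1.085, 0.718),
        (8, 107, 0, 107, 0.773, 0.008, 0.997, 0.597),
    ]
    return [
        BridgeModel(intercept=a, slope=b, r=r, r_squared=r2, n=n,
                    min_fullgen=k, n_goats=ng, n_sheep=ns)
        for k, n, ng, ns, r, a, b, r2 in rows
    ]


@pytest.fixture(scope="session")
def small_sim_bundle():
    """One modest simulated herd reused across tests (seeded)."""
    from rohbridge.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_founders=20, generations=4, sires_per_generation=3,
                    dams_per_generation=8, n_chromosomes=3,
                    snps_per_chromosome=400, chromosome_length_mb=80,
                    seed=42, missing_rate=0.01)
    return simulate_dataset(cfg)
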