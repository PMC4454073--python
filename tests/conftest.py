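"""Shared fixtures: the synthetic benchmark, calibrated family profiles,
and an independent brute-force path enumerator for profile HMMs."""

from __future__ import annotations

import numpy as np
import pytest

from ampyscan.phmm import ProfileHMM, build_profile, calibrate_evalue
from ampyscan.synth import default_benchmark

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    return default_benchmark(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_profiles(benchmark):
    """Calibrated per-family profiles built from the true seed alignments."""
    profiles = {}
    for i, (name, aln) in enumerate(sorted(benchmark.alignments.items())):
        profile = build_profile(aln, name=name)
        calibrate_evalue(profile, n_random=100, seed=100 + i)
        profiles[name] = profile
    return profiles


# --- independent oracle: exhaustive path enumeration ----------------------

def enumerate_path_probs(profile: ProfileHMM, codes: list[int]) -> list[float]:
    """Probability of every complete state path that emits the sequence.

    Walks the architecture explicitly: N flank (emit on self-loop), the
    begin state, the match/insert/delete chain, the end state, C flank.
    Independent of the dynamic-programming implementation; exponential in
    sequence length, so only usable for tiny models.
    """
    L = profile.L
    n = len(codes)
    q = list(profile.background) + [1.0]  # X emits with probability 1
    em = [list(row) + [1.0] for row in profile.match_emit]
    ei = [list(row) + [1.0] for row in profile.insert_emit]
    loop, exit_ = profile.flank_loop, 1.0 - profile.flank_loop
    out: list[float] = []

    def cflank(i: int, p: float) -> None:
        # C flank consumes the remaining residues one per self-loop
        prob = p
        for t in range(i, n):
            prob *= loop * q[codes[t]]
        out.append(prob * exit_)

    def walk(state: str, k: int, i: int, p: float) -> None:
        if p == 0.0:
            return
        if state == "M":  # M_k with k==0 meaning B
            tm, ti, td = profile.t_mm[k], profile.t_mi[k], profile.t_md[k]
        elif state == "I":
            tm, ti, td = profile.t_im[k], profile.t_ii[k], profile.t_id[k]
        else:
            tm, ti, td = profile.t_dm[k], profile.t_di[k], profile.t_dd[k]
        # to M_{k+1} (or E when k == L)
        if k == L:
            cflank(i, p * tm)
        elif i < n:
            walk("M", k + 1, i + 1, p * tm * em[k + 1][codes[i]])
        if i < n and ti > 0:
            walk("I", k, i + 1, p * ti * ei[k][codes[i]])
        if k < L and td > 0:
            walk("D", k + 1, i, p * td)

    for j in range(n + 1):  # N flank emits the first j residues
        p = exit_
        for t in range(j):
            p *= loop * q[codes[t]]
        walk("M", 0, j, p)
    return out


def random_profile(L: int, seed: int) -> ProfileHMM:
    """A random valid profile with all transitions strictly positive."""
    rng = np.random.default_rng(seed)

    def dirichlet(size, cols):
        return rng.dirichlet(np.ones(cols), size=size)

    match_emit = np.zeros((L + 1, 20))
    match_emit[1:] = dirichlet(L, 20)
    insert_emit = dirichlet(L + 1, 20)
    tm = dirichlet(L + 1, 3)
    ti = dirichlet(L + 1, 3)
    td = dirichlet(L + 1, 3)
    # no D_{L+1}: fold its mass into the M target
    for t in (tm, ti, td):
        t[L, 0] += t[L, 2]
        t[L, 2] = 0.0
    td[0] = 0.0
    profile = ProfileHMM(
        name=f"random-L{L}",
        match_emit=match_emit,
        insert_emit=insert_emit,
        t_mm=tm[:, 0], t_mi=tm[:, 1], t_md=tm[:, 2],
        t_im=ti[:, 0], t_ii=ti[:, 1], t_id=ti[:, 2],
        t_dm=td[:, 0], t_di=td[:, 1], t_dd=td[:, 2],
        background=np.full(20, 0.05),
        flank_loop=0.6,
        typical_length=max(L, 2),
    )
    profile.validate()
    return profile
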