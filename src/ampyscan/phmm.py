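"""Profile hidden Markov models for protein-family classification.

A profile is built from a seed multiple sequence alignment: columns with a
gap fraction <= 0.5 become match states, the rest feed insert states.  The
architecture is the classical match/insert/delete chain (Durbin-style)
flanked by self-looping background-emitting states on both sides, so a
family domain is found anywhere inside a longer query (local in sequence,
global in model; no multi-domain re-entry).

Scores are log2-odds ("bit") scores of the forward probability against an
i.i.d. background null of the same length.  E-values come from a Gumbel
(extreme-value) fit to the forward scores of background-sampled sequences,
mirroring the calibration strategy of HMMER-style search tools.

State/transition layout (probability arrays, index k):

* ``t_mm[k]`` M_k -> M_{k+1} for k=0..L, where M_0 is the begin state B and
  M_{L+1} is the end state E; ``t_mi[k]`` M_k -> I_k; ``t_md[k]`` M_k -> D_{k+1}.
* ``t_im / t_ii / t_id`` likewise from insert states I_0..I_L.
* ``t_dm / t_di / t_dd`` from delete states D_1..D_L (index 0 unused).
* The flanking states N (before B) and C (after E) emit background
  residues on their self-loops with probability ``flank_loop``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
from scipy.stats import gumbel_r

from .seqio import AMINO_ACIDS, GAP, Alignment, SequenceRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_LN2 = math.log(2.0)
_NEG_INF = float("-inf")


def _log(x: np.ndarray | float):
    with np.errstate(divide="ignore"):
        return np.log(x)


@dataclass
class Calibration:
    loc: float
    scale: float
    n_random: int
    seed: int
    length: int


@dataclass
class ProfileHMM:
    """Profile HMM with explicit probability parameterisation."""

    name: str
    match_emit: np.ndarray  # (L+1, 20); row 0 unused
    insert_emit: np.ndarray  # (L+1, 20) for I_0..I_L
    t_mm: np.ndarray  # (L+1,)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_id: np.ndarray
    t_dm: np.ndarray
    t_di: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray  # (20,)
    flank_loop: float = 0.99
    typical_length: int = 100
    reference_map: dict[int, int] = field(default_factory=dict)  # match k -> ref pos (1-based)
    calibration: Calibration | None = None

    @property
    def L(self) -> int:
        return self.match_emit.shape[0] - 1

    def validate(self, tol: float = 1e-9) -> None:
        """Check that all emission and outgoing-transition rows sum to 1."""
        L = self.L
        for k in range(1, L + 1):
            if abs(self.match_emit[k].sum() - 1) > tol:
                raise ValueError(f"match emissions at state {k} do not sum to 1")
        for k in range(L + 1):
            if abs(self.insert_emit[k].sum() - 1) > tol:
                raise ValueError(f"insert emissions at state {k} do not sum to 1")
        for k in range(L + 1):
            if abs(self.t_mm[k] + self.t_mi[k] + self.t_md[k] - 1) > tol:
                raise ValueError(f"M_{k} outgoing transitions do not sum to 1")
            if abs(self.t_im[k] + self.t_ii[k] + self.t_id[k] - 1) > tol:
                raise ValueError(f"I_{k} outgoing transitions do not sum to 1")
        for k in range(1, L + 1):
            if abs(self.t_dm[k] + self.t_di[k] + self.t_dd[k] - 1) > tol:
                raise ValueError(f"D_{k} outgoing transitions do not sum to 1")
        if abs(self.background.sum() - 1) > tol:
            raise ValueError("background does not sum to 1")

    def match_state_for_reference_position(self, pos: int) -> int:
        """Match-state index whose column carries reference position *pos*."""
        for k, p in self.reference_map.items():
            if p == pos:
                return k
        raise KeyError(f"reference position {pos} is not mapped to a match state")

    # --- serialisation ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "ampyscan-phmm-v1",
            "name": self.name,
            "match_emit": self.match_emit.tolist(),
            "insert_emit": self.insert_emit.tolist(),
            "transitions": {
                t: getattr(self, t).tolist()
                for t in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_id", "t_dm", "t_di", "t_dd")
            },
            "background": self.background.tolist(),
            "flank_loop": self.flank_loop,
            "typical_length": self.typical_length,
            "reference_map": {str(k): v for k, v in self.reference_map.items()},
            "calibration": vars(self.calibration) if self.calibration else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ProfileHMM":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ampyscan-phmm-v1":
            raise ValueError("not an ampyscan profile file")
        trans = {t: np.array(v) for t, v in payload["transitions"].items()}
        cal = payload["calibration"]
        return cls(
            name=payload["name"],
            match_emit=np.array(payload["match_emit"]),
            insert_emit=np.array(payload["insert_emit"]),
            background=np.array(payload["background"]),
            flank_loop=payload["flank_loop"],
            typical_length=payload["typical_length"],
            reference_map={int(k): v for k, v in payload["reference_map"].items()},
            calibration=Calibration(**cal) if cal else None,
            **trans,
        )


@dataclass
class HmmHit:
    """One profile-vs-sequence hit from a scan."""

    seq_id: str
    family: str
    bitscore: float
    evalue: float
    qstart: int | None = None  # 1-based, inclusive span of the aligned core
    qend: int | None = None
    # match-state index -> 1-based query position (Viterbi correspondence)
    correspondence: dict[int, int] = field(default_factory=dict)


@dataclass
class ViterbiAlignment:
    score: float  # bits
    correspondence: dict[int, int]
    qstart: int | None
    qend: int | None


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


# --- profile construction -------------------------------------------------

def build_profile(
    msa: Alignment,
    pseudocount_weight: float = 1.0,
    name: str = "family",
    background: np.ndarray | None = None,
    match_gap_fraction: float = 0.5,
    flank_loop: float = 0.99,
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Match columns are those with gap fraction <= *match_gap_fraction*.
    Emissions use background-weighted pseudocounts,
    ``(counts + alpha * q) / (total + alpha)``; transitions are estimated
    from the observed per-row state paths with Laplace pseudocounts.  The
    reference map records, for each match state, the 1-based position it
    occupies in the designated reference row.
    """
    if msa.nrows < 2:
        raise ValueError("seed alignment needs at least 2 rows")
    q = background if background is not None else uniform_background()
    alpha = float(pseudocount_weight)
    ncols, nrows = msa.ncols, msa.nrows
    cols = [[row[j] for row in msa.rows] for j in range(ncols)]
    is_match = [sum(c == GAP for c in col) / nrows <= match_gap_fraction for col in cols]
    L = sum(is_match)
    if L == 0:
        raise ValueError("alignment has no match columns")

    match_counts = np.zeros((L + 1, 20))
    insert_counts = np.zeros((L + 1, 20))
    # transition counts; order of targets per source: (M, I, D)
    tc = {s: np.zeros((L + 1, 3)) for s in "MID"}

    for row in msa.rows:
        state, k = "M", 0  # M_0 == B
        for j in range(ncols):
            c = row[j]
            if is_match[j]:
                nk = k + 1
                if c == GAP:
                    tc[state][k, 2] += 1
                    state = "D"
                else:
                    tc[state][k, 0] += 1
                    state = "M"
                    if c in _AA_INDEX:
                        match_counts[nk, _AA_INDEX[c]] += 1
                k = nk
            else:
                if c != GAP:
                    tc[state][k, 1] += 1
                    state = "I"
                    if c in _AA_INDEX:
                        insert_counts[k, _AA_INDEX[c]] += 1
        tc[state][k, 0] += 1  # exit to E

    match_emit = np.zeros((L + 1, 20))
    match_emit[1:] = (match_counts[1:] + alpha * q) / (
        match_counts[1:].sum(axis=1, keepdims=True) + alpha
    )
    insert_emit = (insert_counts + alpha * q) / (
        insert_counts.sum(axis=1, keepdims=True) + alpha
    )

    def norm(counts: np.ndarray, k: int, allowed: tuple[bool, bool, bool]) -> np.ndarray:
        c = counts[k] + np.array([1.0 if a else 0.0 for a in allowed])
        c = c * np.array([1.0 if a else 0.0 for a in allowed])
        return c / c.sum()

    last = L  # at k=L, D-target does not exist
    t = {s: np.zeros((L + 1, 3)) for s in "MID"}
    for k in range(L + 1):
        allowed = (True, True, k < last)
        t["M"][k] = norm(tc["M"], k, allowed)
        t["I"][k] = norm(tc["I"], k, allowed)
        if 1 <= k:
            t["D"][k] = norm(tc["D"], k, allowed)

    ref_row = msa.rows[msa.reference_row()]
    reference_map: dict[int, int] = {}
    k = 0
    rpos = 0
    for j in range(ncols):
        c = ref_row[j]
        if c != GAP:
            rpos += 1
        if is_match[j]:
            k += 1
            if c != GAP:
                reference_map[k] = rpos

    lengths = [len(row.replace(GAP, "")) for row in msa.rows]
    profile = ProfileHMM(
        name=name,
        match_emit=match_emit,
        insert_emit=insert_emit,
        t_mm=t["M"][:, 0].copy(),
        t_mi=t["M"][:, 1].copy(),
        t_md=t["M"][:, 2].copy(),
        t_im=t["I"][:, 0].copy(),
        t_ii=t["I"][:, 1].copy(),
        t_id=t["I"][:, 2].copy(),
        t_dm=t["D"][:, 0].copy(),
        t_di=t["D"][:, 1].copy(),
        t_dd=t["D"][:, 2].copy(),
        background=q,
        flank_loop=flank_loop,
        typical_length=int(round(float(np.median(lengths)))),
        reference_map=reference_map,
    )
    profile.validate()
    return profile


# --- scoring --------------------------------------------------------------

def _encode(seq: SequenceRecord | str) -> list[int]:
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    return [_AA_INDEX.get(c, -1) for c in residues]  # -1 = X (ignored residue)


def _emission_logs(profile: ProfileHMM):
    """Log emission tables with an extra column for X scoring log(1)=0.

    X residues are treated as uninformative: they contribute probability 1
    under every emitting state and under the null, so their log-odds is 0.
    """
    cached = profile.__dict__.get("_emlog_cache")
    if cached is not None:
        return cached
    lem = np.hstack([_log(profile.match_emit), np.zeros((profile.L + 1, 1))])
    lei = np.hstack([_log(profile.insert_emit), np.zeros((profile.L + 1, 1))])
    lq = np.append(_log(profile.background), 0.0)
    profile.__dict__["_emlog_cache"] = (lem, lei, lq)
    return lem, lei, lq


_TRANS_NAMES = ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_id", "t_dm", "t_di", "t_dd")


def _transition_logs(profile: ProfileHMM) -> list[list[float]]:
    cached = profile.__dict__.get("_trlog_cache")
    if cached is None:
        cached = [_log(getattr(profile, name)).tolist() for name in _TRANS_NAMES]
        profile.__dict__["_trlog_cache"] = cached
    return cached


def null_log_prob(profile: ProfileHMM, seq: SequenceRecord | str) -> float:
    """ln P(seq | i.i.d. background null)."""
    _, _, lq = _emission_logs(profile)
    return float(sum(lq[c] for c in _encode(seq)))


def forward_score(profile: ProfileHMM, seq: SequenceRecord | str) -> float:
    """Forward bit score: log2 of P(seq | model) / P(seq | null)."""
    lnp = forward_log_prob(profile, seq)
    return (lnp - null_log_prob(profile, seq)) / _LN2


def forward_log_prob(profile: ProfileHMM, seq: SequenceRecord | str) -> float:
    """ln P(seq | model) by the forward recursion over the full architecture."""
    codes = _encode(seq)
    n, L = len(codes), profile.L
    cached = profile.__dict__.get("_fwd_cache")
    if cached is None:
        lem_a, lei_a, lq_a = _emission_logs(profile)
        cached = (lem_a.tolist(), lei_a.tolist(), lq_a.tolist())
        profile.__dict__["_fwd_cache"] = cached
    lem, lei, lq = cached
    l_loop = math.log(profile.flank_loop)
    l_exit = math.log(1.0 - profile.flank_loop)
    t_mm, t_mi, t_md, t_im, t_ii, t_id, t_dm, t_di, t_dd = _transition_logs(profile)
    log, exp = math.log, math.exp

    def lse3(a: float, b: float, c: float) -> float:
        m = a if a >= b else b
        if c > m:
            m = c
        if m == _NEG_INF:
            return _NEG_INF
        return m + log(exp(a - m) + exp(b - m) + exp(c - m))

    # fM[k]: k=0 is the begin state B (reached from the N flank)
    fM = [_NEG_INF] * (L + 1)
    fI = [_NEG_INF] * (L + 1)
    fD = [_NEG_INF] * (L + 1)
    fM[0] = l_exit  # N exited before emitting anything
    for k in range(1, L + 1):
        fD[k] = lse3(
            fM[k - 1] + t_md[k - 1],
            fI[k - 1] + t_id[k - 1],
            fD[k - 1] + t_dd[k - 1] if k >= 2 else _NEG_INF,
        )
    fN = 0.0

    def end_score(fM, fI, fD):
        return lse3(fM[L] + t_mm[L], fI[L] + t_im[L], fD[L] + t_dm[L])

    fC = end_score(fM, fI, fD)
    for i in range(1, n + 1):
        x = codes[i - 1]
        pM, pI, pD = fM, fI, fD
        fM = [_NEG_INF] * (L + 1)
        fI = [_NEG_INF] * (L + 1)
        fD = [_NEG_INF] * (L + 1)
        fN = fN + l_loop + lq[x]
        fM[0] = fN + l_exit
        emk = [row[x] for row in lem]
        eik = [row[x] for row in lei]
        for k in range(1, L + 1):
            fM[k] = emk[k] + lse3(
                pM[k - 1] + t_mm[k - 1],
                pI[k - 1] + t_im[k - 1],
                pD[k - 1] + t_dm[k - 1] if k >= 2 else _NEG_INF,
            )
        for k in range(L + 1):
            fI[k] = eik[k] + lse3(
                pM[k] + t_mi[k],
                pI[k] + t_ii[k],
                pD[k] + t_di[k] if k >= 1 else _NEG_INF,
            )
        for k in range(1, L + 1):
            fD[k] = lse3(
                fM[k - 1] + t_md[k - 1],
                fI[k - 1] + t_id[k - 1],
                fD[k - 1] + t_dd[k - 1] if k >= 2 else _NEG_INF,
            )
        # C flank: entered at E after i emissions, or looping while emitting
        fC = lse3(end_score(fM, fI, fD), fC + l_loop + lq[x], _NEG_INF)
    return fC + l_exit


def viterbi_align(profile: ProfileHMM, seq: SequenceRecord | str) -> ViterbiAlignment:
    """Best state path (max-product analogue of forward) with traceback.

    Ties are broken by preferring match over delete over insert
    predecessors.  Returns the bit score of the best path and the
    match-state-to-query-position correspondence along it.
    """
    codes = _encode(seq)
    n, L = len(codes), profile.L
    lem_a, lei_a, lq_a = _emission_logs(profile)
    lem, lei, lq = lem_a.tolist(), lei_a.tolist(), lq_a.tolist()
    l_loop = math.log(profile.flank_loop)
    l_exit = math.log(1.0 - profile.flank_loop)
    t_mm, t_mi, t_md, t_im, t_ii, t_id, t_dm, t_di, t_dd = _transition_logs(profile)

    # DP tables over (i, k); backpointers: 0=M/B, 1=I, 2=D
    vM = [[_NEG_INF] * (L + 1) for _ in range(n + 1)]
    vI = [[_NEG_INF] * (L + 1) for _ in range(n + 1)]
    vD = [[_NEG_INF] * (L + 1) for _ in range(n + 1)]
    bM = [[0] * (L + 1) for _ in range(n + 1)]
    bI = [[0] * (L + 1) for _ in range(n + 1)]
    bD = [[0] * (L + 1) for _ in range(n + 1)]

    def pick(m: float, d: float, i_: float) -> tuple[float, int]:
        # preference order M > D > I on exact ties
        best, ptr = m, 0
        if d > best:
            best, ptr = d, 2
        if i_ > best:
            best, ptr = i_, 1
        return best, ptr

    flank = l_exit
    for i in range(n + 1):
        vM[i][0] = flank
        if i < n:
            flank += l_loop + lq[codes[i]]
    for i in range(n + 1):
        x = codes[i - 1] if i >= 1 else -1
        vMi, vIi, vDi = vM[i], vI[i], vD[i]
        bMi, bIi, bDi = bM[i], bI[i], bD[i]
        if i >= 1:
            pMi, pIi, pDi = vM[i - 1], vI[i - 1], vD[i - 1]
            for k in range(L + 1):
                s, ptr = pick(
                    pMi[k] + t_mi[k],
                    pDi[k] + t_di[k] if k >= 1 else _NEG_INF,
                    pIi[k] + t_ii[k],
                )
                vIi[k] = lei[k][x] + s
                bIi[k] = ptr
        for k in range(1, L + 1):
            if i >= 1:
                s, ptr = pick(
                    pMi[k - 1] + t_mm[k - 1],
                    pDi[k - 1] + t_dm[k - 1] if k >= 2 else _NEG_INF,
                    pIi[k - 1] + t_im[k - 1],
                )
                vMi[k] = lem[k][x] + s
                bMi[k] = ptr
            s, ptr = pick(
                vMi[k - 1] + t_md[k - 1],
                vDi[k - 1] + t_dd[k - 1] if k >= 2 else _NEG_INF,
                vIi[k - 1] + t_id[k - 1],
            )
            vDi[k] = s
            bDi[k] = ptr

    # end: E reached from (M|I|D)_L at some i, then C flank emits the rest
    best_total, best_i, best_ptr = _NEG_INF, None, 0
    suffix = 0.0
    csuffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix += l_loop + lq[codes[i]]
        csuffix[i] = suffix
    for i in range(n + 1):
        s, ptr = pick(
            vM[i][L] + t_mm[L],
            vD[i][L] + t_dm[L],
            vI[i][L] + t_im[L],
        )
        total = s + csuffix[i] + l_exit
        if total > best_total:
            best_total, best_i, best_ptr = total, i, ptr

    if best_total == _NEG_INF:
        return ViterbiAlignment(score=_NEG_INF, correspondence={}, qstart=None, qend=None)

    # traceback through the core
    correspondence: dict[int, int] = {}
    emitted: list[int] = []
    state, i, k = best_ptr, best_i, L
    while k > 0 or state != 0:
        if state == 0:  # M_k (k>=1) or B
            if k == 0:
                break
            correspondence[k] = i
            emitted.append(i)
            ptr = bM[i][k]
            i, k, state = i - 1, k - 1, ptr
        elif state == 2:  # D_k
            ptr = bD[i][k]
            k, state = k - 1, ptr
        else:  # I_k
            emitted.append(i)
            ptr = bI[i][k]
            i, state = i - 1, ptr
    score_bits = (best_total - null_log_prob(profile, seq)) / _LN2
    qstart = min(emitted) if emitted else None
    qend = max(emitted) if emitted else None
    return ViterbiAlignment(score=score_bits, correspondence=correspondence, qstart=qstart, qend=qend)


# --- calibration and scanning ---------------------------------------------

def sample_background(profile: ProfileHMM, length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=profile.background)
    return "".join(AMINO_ACIDS[i] for i in idx)


def calibrate_evalue(
    profile: ProfileHMM,
    n_random: int = 200,
    seed: int = 0,
    length: int | None = None,
) -> ProfileHMM:
    """Fit a Gumbel null distribution to background forward scores (in place).

    *n_random* background sequences of the profile's typical family length
    are sampled and scored; their bit scores are fit by an extreme-value
    (Gumbel) distribution whose survival function converts scores to
    E-values.
    """
    if n_random < 50:
        raise ValueError("n_random must be >= 50")
    length = length or profile.typical_length
    rng = np.random.default_rng(seed)
    scores = np.array(
        [forward_score(profile, sample_background(profile, length, rng)) for _ in range(n_random)]
    )
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate null score distribution; cannot calibrate")
    loc, scale = gumbel_r.fit(scores)
    profile.calibration = Calibration(
        loc=float(loc), scale=float(scale), n_random=n_random, seed=seed, length=length
    )
    return profile


def evalue(profile: ProfileHMM, bitscore: float, n_targets: int) -> float:
    """Expected number of >= bitscore hits among n_targets null sequences."""
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    cal = profile.calibration
    return float(n_targets) * float(gumbel_r.sf(bitscore, loc=cal.loc, scale=cal.scale))


def scan(
    seqs: Sequence[SequenceRecord],
    profiles: Sequence[ProfileHMM],
    e_cutoff: float = 1e-3,
    n_targets: int | None = None,
    align: bool = True,
) -> list[HmmHit]:
    """Score every profile against every sequence; keep hits with E <= cutoff.

    The default cutoff mirrors the conservative dataset-compilation setting
    (1e-3); remote-homolog screens such as the AnkX CMP-binding search use
    a permissive cutoff of 1.  With ``align=True`` each hit carries its
    Viterbi span and match-state correspondence.
    """
    n_targets = n_targets if n_targets is not None else max(len(seqs), 1)
    hits: list[HmmHit] = []
    for profile in profiles:
        if profile.calibration is None:
            raise ValueError(f"profile {profile.name!r} is not calibrated")
        for seq in seqs:
            bits = forward_score(profile, seq)
            e = evalue(profile, bits, n_targets)
            if e <= e_cutoff:
                hit = HmmHit(seq_id=seq.id, family=profile.name, bitscore=bits, evalue=e)
                if align:
                    va = viterbi_align(profile, seq)
                    hit.qstart, hit.qend = va.qstart, va.qend
                    hit.correspondence = va.correspondence
                hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.family, h.seq_id))
    return hits


@dataclass
class FamilyCall:
    seq_id: str
    label: str  # family name or "unclassified"
    margin: float | None = None  # second-best E minus best E
    best_hit: HmmHit | None = None


def classify_family(hits: Sequence[HmmHit]) -> FamilyCall:
    """Assign the family of the minimum-E-value hit for one sequence.

    Ties break by bit score (higher wins) then profile name.  With no
    passing hits the sequence is "unclassified".
    """
    ids = {h.seq_id for h in hits}
    if len(ids) > 1:
        raise ValueError("classify_family expects hits for a single sequence")
    if not hits:
        return FamilyCall(seq_id="", label="unclassified")
    ordered = sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.family))
    best = ordered[0]
    margin = (ordered[1].evalue - best.evalue) if len(ordered) > 1 else None
    return FamilyCall(seq_id=best.seq_id, label=best.family, margin=margin, best_hit=best)
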