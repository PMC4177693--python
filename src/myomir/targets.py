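"""Seed-match target prediction and shared-target statistics.

A 3'UTR is a target of a miRNA when it carries at least one canonical seed
site: 7mer-m8 (Watson-Crick match to mature positions 2-8), 7mer-A1 (match to
positions 2-7 followed by an A opposite position 1), or 8mer (both). Two
miRNAs' target sets are compared by the fraction shared relative to the
smaller set (plus Jaccard), and the excess overlap is judged against a null
of randomly drawn miRNA pairs from a pool, giving an add-one-corrected
empirical p-value. Seed matching is the entire site model here - no
conservation weighting or context scoring - so identical-seed miRNAs share
their targets exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import revcomp

_RNA2DNA = str.maketrans("Uu", "Tt")


@dataclass
class SeedSite:
    utr_id: str
    position: int  # 1-based, 5'-most UTR nucleotide of the site
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"


def _norm(seq: str) -> str:
    return seq.upper().translate(_RNA2DNA)


def find_seed_sites(mature: str, utrs: dict[str, str]) -> list[SeedSite]:
    """All canonical seed sites of ``mature`` in a UTR set (plus strand only).

    UTRs shorter than 7 nt are skipped. Positions are 1-based on the UTR.
    """
    m = _norm(mature)
    if len(m) < 8:
        raise ValueError("mature sequence must be >= 8 nt")
    seed7 = m[1:8]            # positions 2-8
    site_m8 = revcomp(seed7)  # 7 nt
    site_a1 = revcomp(m[1:7]) + "A"  # 6-mer match + A1 anchor, 7 nt
    out: list[SeedSite] = []
    for uid, seq0 in utrs.items():
        seq = _norm(seq0)
        if len(seq) < 7:
            continue
        found_8mer_at: set[int] = set()
        start = 0
        while True:
            p = seq.find(site_m8, start)
            if p < 0:
                break
            if seq[p + 7: p + 8] == "A":
                out.append(SeedSite(uid, p + 1, "8mer"))
                found_8mer_at.add(p)
            else:
                out.append(SeedSite(uid, p + 1, "7mer-m8"))
            start = p + 1
        start = 0
        while True:
            p = seq.find(site_a1, start)
            if p < 0:
                break
            # an 8mer starting one nt 5' already covers this 7mer-A1
            if (p - 1) not in found_8mer_at:
                out.append(SeedSite(uid, p + 1, "7mer-A1"))
            start = p + 1
    return sorted(out, key=lambda s: (s.utr_id, s.position, s.site_type))


def target_set(mature: str, utrs: dict[str, str]) -> set[str]:
    """UTR ids with at least one canonical site."""
    return {s.utr_id for s in find_seed_sites(mature, utrs)}


@dataclass
class OverlapStat:
    n_a: int
    n_b: int
    intersection: int
    shared_fraction: float  # |A & B| / min(|A|, |B|)
    jaccard: float


def overlap_stat(a: set[str], b: set[str]) -> OverlapStat:
    inter = len(a & b)
    union = len(a | b)
    if not a or not b:
        if not a or not b:
            warnings.warn("a miRNA has zero targets; shared fraction set to 0")
        frac = 0.0
    else:
        frac = inter / min(len(a), len(b))
    return OverlapStat(
        n_a=len(a), n_b=len(b), intersection=inter,
        shared_fraction=frac, jaccard=(inter / union if union else 0.0),
    )


def shared_target_fraction(
    mature_a: str, mature_b: str, utrs: dict[str, str]
) -> OverlapStat:
    """Shared-target statistics for one miRNA pair on a UTR set."""
    return overlap_stat(target_set(mature_a, utrs), target_set(mature_b, utrs))


@dataclass
class PermutationResult:
    observed: float
    null: list[float]
    p_value: float
    n_perm: int
    seed: int

    def summary(self) -> dict:
        null = np.asarray(self.null)
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_mean": float(null.mean()) if null.size else 0.0,
            "null_q95": float(np.quantile(null, 0.95)) if null.size else 0.0,
        }


def random_pair_null(
    mature_a: str,
    mature_b: str,
    pool: dict[str, str],
    utrs: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    target_sets: dict | None = None,
) -> PermutationResult:
    """Permutation test: is the focal pair's shared-target fraction larger
    than that of random miRNA pairs?

    Each permutation draws two distinct matures uniformly from ``pool`` and
    computes the same shared-fraction statistic; the empirical p-value uses
    the add-one correction ``(1 + #{null >= obs}) / (1 + n_perm)``.
    ``target_sets`` optionally caches precomputed ``target_set`` results by
    mature sequence (repeated-call efficiency; results are unchanged).
    """
    if len(pool) < 3:
        raise ValueError("pool must contain at least 3 matures")
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    cache = target_sets if target_sets is not None else {}

    def tset(seq: str) -> set[str]:
        if seq not in cache:
            cache[seq] = target_set(seq, utrs)
        return cache[seq]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = overlap_stat(tset(mature_a), tset(mature_b)).shared_fraction
    names = sorted(pool)
    tsets = {n: tset(pool[n]) for n in names}
    rng = np.random.default_rng(seed)
    null: list[float] = []
    for _ in range(n_perm):
        i, j = rng.choice(len(names), size=2, replace=False)
        null.append(
            overlap_stat(tsets[names[int(i)]], tsets[names[int(j)]]).shared_fraction
        )
    p = (1 + sum(1 for v in null if v >= observed)) / (1 + n_perm)
    return PermutationResult(
        observed=observed, null=null, p_value=float(p),
        n_perm=n_perm, seed=seed,
    )
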