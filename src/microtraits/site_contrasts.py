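"""Permutation tests for between-site differences in mean trait values.

For each trait and each pair of body sites the test statistic is the
difference of the per-site means of the per-sample abundance-weighted trait
values.  Site labels are permuted over samples to obtain the null, with an
add-one estimator so the smallest attainable p is 1/(B+1).  Repeated samples
from the same subject are de-duplicated first (one sample per subject and
site).  The Benjamini-Hochberg step-up procedure controls FDR within each
phylum's family of trait x site-pair tests, and a contrast is treated as
ecologically informative when it replicates (is BH-significant) in at least
two phyla.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community_profiles import SampleMetadata, TraitProfileMatrix

__all__ = [
    "ContrastResult",
    "ReplicatedContrast",
    "subsample_one_per_subject",
    "permutation_site_contrast",
    "all_site_contrasts",
    "bh_adjust",
    "replicate_across_phyla",
    "contrasts_to_frame",
]


@dataclass
class ContrastResult:
    """Permutation-test result for one trait and one site pair."""

    trait: str
    site_a: str
    site_b: str
    diff: float  # observed mean(site_a) - mean(site_b)
    p: float | None
    n_a: int
    n_b: int
    n_perm: int
    q: float | None = None
    testable: bool = True


def subsample_one_per_subject(meta: SampleMetadata, seed: int) -> list[str]:
    """Retain exactly one sample per (subject, body site), chosen uniformly."""
    rng = np.random.default_rng(seed)
    retained: list[str] = []
    df = meta.data
    for _, grp in df.groupby(["subject_id", "body_site"], sort=True):
        ids = list(grp.index)
        retained.append(ids[rng.integers(len(ids))] if len(ids) > 1 else ids[0])
    return sorted(retained)


def permutation_site_contrast(
    profiles: TraitProfileMatrix,
    meta: SampleMetadata,
    trait: str,
    site_a: str,
    site_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ContrastResult:
    """Two-sided permutation test for a difference in mean trait value.

    p = (1 + #{permuted |diff| >= observed |diff|}) / (n_perm + 1).
    Requires at least two non-missing profile values per site; otherwise the
    result is flagged untestable with no p.
    """
    row = profiles.values.loc[trait]
    sites = meta.site_of().reindex(profiles.samples)
    a = row[(sites == site_a).to_numpy()].dropna().to_numpy(dtype=float)
    b = row[(sites == site_b).to_numpy()].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        return ContrastResult(
            trait, site_a, site_b,
            float(a.mean() - b.mean()) if len(a) and len(b) else float("nan"),
            None, len(a), len(b), n_perm, testable=False,
        )
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    total = pooled.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    abs_obs = abs(observed)
    # permuted diff depends only on the sum over the group-A positions
    for start in range(0, n_perm, 2048):
        k = min(2048, n_perm - start)
        keys = rng.random((k, pooled.size))
        take = keys.argpartition(n_a - 1, axis=1)[:, :n_a]
        s_a = pooled[take].sum(axis=1)
        d = s_a / n_a - (total - s_a) / n_b
        hits += int((np.abs(d) >= abs_obs - 1e-12).sum())
    p = (1 + hits) / (n_perm + 1)
    return ContrastResult(trait, site_a, site_b, observed, p, n_a, len(b), n_perm)


def all_site_contrasts(
    profiles: TraitProfileMatrix,
    meta: SampleMetadata,
    sites: Sequence[str] | None = None,
    traits: Sequence[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """All pairwise site contrasts for all traits, BH-adjusted as one family."""
    sites = list(sites) if sites is not None else sorted(
        meta.site_of().reindex(profiles.samples).dropna().unique()
    )
    traits = list(traits) if traits is not None else list(profiles.traits)
    rng = np.random.default_rng(seed)
    results: list[ContrastResult] = []
    for trait in traits:
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                results.append(
                    permutation_site_contrast(
                        profiles, meta, trait, sites[i], sites[j],
                        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                    )
                )
    testable = [r for r in results if r.testable]
    if testable:
        qs, _ = bh_adjust([r.p for r in testable], alpha=alpha)
        for r, q in zip(testable, qs):
            r.q = float(q)
    return results


def bh_adjust(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and the rejection set at ``alpha``.

    Rejection is q <= alpha, equivalent to the classical step-up rule.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class ReplicatedContrast:
    """A trait x site-pair contrast significant in >= 2 phyla."""

    trait: str
    site_a: str
    site_b: str
    phyla: tuple[str, ...]
    signs: tuple[int, ...]
    consensus_sign: int  # 0 when phyla disagree
    sign_conflict: bool = False


def replicate_across_phyla(
    per_phylum: Mapping[str, Sequence[ContrastResult]],
    alpha: float = 0.05,
    min_phyla: int = 2,
) -> list[ReplicatedContrast]:
    """Keep contrasts BH-significant in at least ``min_phyla`` phyla.

    Sign conflicts across phyla are retained but flagged rather than merged.
    """
    hits: dict[tuple[str, str, str], list[tuple[str, int]]] = {}
    for phylum, results in per_phylum.items():
        for r in results:
            if r.testable and r.q is not None and r.q <= alpha:
                key = (r.trait, r.site_a, r.site_b)
                hits.setdefault(key, []).append((phylum, int(np.sign(r.diff))))
    out = []
    for (trait, a, b), entries in sorted(hits.items()):
        if len(entries) < min_phyla:
            continue
        phyla = tuple(e[0] for e in entries)
        signs = tuple(e[1] for e in entries)
        uniq = set(s for s in signs if s != 0)
        conflict = len(uniq) > 1
        consensus = 0 if conflict or not uniq else uniq.pop()
        out.append(
            ReplicatedContrast(trait, a, b, phyla, signs, consensus, conflict)
        )
    return out


def contrasts_to_frame(
    results: Sequence[ContrastResult], phylum: str | None = None
) -> pd.DataFrame:
    """Tidy table (trait, siteA, siteB, phylum, diff, p, q, n_A, n_B)."""
    return pd.DataFrame(
        {
            "trait": [r.trait for r in results],
            "siteA": [r.site_a for r in results],
            "siteB": [r.site_b for r in results],
            "phylum": phylum or "all",
            "diff": [r.diff for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "n_A": [r.n_a for r in results],
            "n_B": [r.n_b for r in results],
        }
    )
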