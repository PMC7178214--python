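"""Permutation significance of the overlap between two gene lists.

Draw ``|query|`` genes uniformly without replacement from the background
``n_perm`` times and count the draws whose overlap with the fixed reference
list reaches the observed overlap; the add-one estimator

    p_empirical = (1 + #{overlap >= observed}) / (n_perm + 1)

never returns zero (ties count as exceedances).  The exact upper tail of
the matching Hypergeometric(N, K, n) distribution is computed alongside as
an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = ["OverlapResult", "permutation_overlap"]

# cap on the random-key matrix size per chunk (elements), keeps memory flat
_MAX_CHUNK_ELEMS = 16_000_000


@dataclass(frozen=True)
class OverlapResult:
    n_background: int
    n_query: int
    n_reference: int
    observed_overlap: int
    n_perm: int
    p_empirical: float
    p_hypergeometric: float
    seed: int


def permutation_overlap(
    background: Iterable[str],
    query: Iterable[str],
    reference: Iterable[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> OverlapResult:
    """Empirical and exact-hypergeometric significance of |query ∩ reference|.

    ``query`` and ``reference`` must both be subsets of ``background``.
    Each permutation draws a uniformly random subset of the background of
    the query's size (a random key per gene, keeping the smallest
    ``|query|`` keys) and records its overlap with the reference.
    """
    bg = sorted(set(background))
    q = set(query)
    ref = set(reference)
    bad_q = sorted(q - set(bg))
    bad_r = sorted(ref - set(bg))
    if bad_q or bad_r:
        raise ValueError(
            f"not contained in background: query {bad_q[:10]}, "
            f"reference {bad_r[:10]}"
        )
    N, n_query, n_ref = len(bg), len(q), len(ref)
    observed = len(q & ref)

    ref_mask = np.fromiter((g in ref for g in bg), dtype=bool, count=N)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    n_exceed = 0
    if n_query == 0:
        n_exceed = n_perm if observed <= 0 else 0
    else:
        chunk = max(1, min(n_perm, _MAX_CHUNK_ELEMS // max(N, 1)))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            keys = rng.random((c, N))
            picked = np.argpartition(keys, n_query - 1, axis=1)[:, :n_query]
            counts = ref_mask[picked].sum(axis=1)
            n_exceed += int((counts >= observed).sum())
            done += c

    p_emp = (1.0 + n_exceed) / (n_perm + 1.0)
    p_hyp = float(stats.hypergeom.sf(observed - 1, N, n_ref, n_query))
    return OverlapResult(
        n_background=N,
        n_query=n_query,
        n_reference=n_ref,
        observed_overlap=observed,
        n_perm=n_perm,
        p_empirical=p_emp,
        p_hypergeometric=p_hyp,
        seed=int(seed),
    )
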