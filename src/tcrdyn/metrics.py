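"""Repertoire-level summary statistics: clonality and cosine similarity.

The clonality index is one minus the normalised Shannon entropy of the
clone-frequency distribution,

    clonality = 1 - H / ln(N),   H = -sum_i p_i ln(p_i),

where ``p_i`` is the frequency of clone *i* and ``N`` the number of
clones.  It is 0 for a perfectly even repertoire and approaches 1 when
one clone dominates.  For N = 1 the denominator vanishes and the score
is undefined rather than an error.

Repertoire similarity is the cosine of the angle between two abundance
vectors indexed by the union of clones of both samples; it is invariant
to sequencing depth (positive rescaling of either vector).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from .io import AbundancePair, Repertoire, abundance_pair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClonalityScore:
    """Normalised-entropy clonality of one repertoire.

    ``value`` is None when the repertoire holds a single clone
    (ln N = 0 makes the index undefined).
    """

    value: float | None
    n_clones: int
    entropy_nats: float

    @property
    def is_defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    n_shared: int
    n_union: int


def clonality(rep: Repertoire) -> ClonalityScore:
    """Clonality index 1 - H/ln(N) with natural-log Shannon entropy H."""
    p = rep.frequencies
    n = rep.n_clones
    h = float(_shannon_entropy(p))  # natural log
    if n < 2:
        return ClonalityScore(value=None, n_clones=n, entropy_nats=h)
    value = 1.0 - h / np.log(n)
    # clip tiny negative rounding noise from H ~ ln N
    return ClonalityScore(value=float(min(max(value, 0.0), 1.0)), n_clones=n, entropy_nats=h)


def cosine_similarity(pair: AbundancePair) -> SimilarityScore:
    """Cosine similarity between paired abundance vectors.

    Raises ValueError on a zero-norm vector (an empty repertoire cannot
    be compared).
    """
    a = pair.counts_a.astype(float)
    b = pair.counts_b.astype(float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm abundance vector")
    value = float(a @ b / (na * nb))
    n_shared = int(np.sum((pair.counts_a > 0) & (pair.counts_b > 0)))
    return SimilarityScore(
        value=float(min(max(value, 0.0), 1.0)),
        n_shared=n_shared,
        n_union=len(pair.union_keys),
    )


def longitudinal_similarity(
    pre: Repertoire, post: Repertoire, key_mode: str = "full_key"
) -> SimilarityScore:
    """Cosine similarity between the pre- and post-treatment repertoires
    of one patient/compartment (pooled across regions upstream)."""
    if pre.meta.patient_id != post.meta.patient_id:
        raise ValueError("longitudinal similarity compares samples of one patient")
    return cosine_similarity(abundance_pair(pre, post, key_mode=key_mode))


def spatial_similarity(
    regions: list[Repertoire], key_mode: str = "full_key"
) -> pd.DataFrame:
    """Pairwise cosine similarity matrix across regions of one timepoint.

    Returns an empty DataFrame (with a logged reason) when fewer than
    two regions are available.  Samples from different timepoints are
    never mixed.
    """
    if len(regions) < 2:
        logger.info("spatial similarity skipped: fewer than 2 regions")
        return pd.DataFrame()
    tps = {r.meta.timepoint for r in regions}
    if len(tps) != 1:
        raise ValueError("spatial similarity is computed within a single timepoint")
    ids = [r.meta.region_id for r in regions]
    mat = pd.DataFrame(np.eye(len(regions)), index=ids, columns=ids)
    for (i, ra), (j, rb) in itertools.combinations(enumerate(regions), 2):
        s = cosine_similarity(abundance_pair(ra, rb, key_mode=key_mode)).value
        mat.iloc[i, j] = s
        mat.iloc[j, i] = s
    return mat
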