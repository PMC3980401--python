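"""Citation-KNN over the average Hausdorff distance, with locality pruning.

A memory-based MIL classifier: a test bag's label is voted on by its R
nearest training bags (*references*) and by the training bags that would
rank the test bag among their own C nearest neighbours (*citers*).  Votes
are unweighted; a tie goes to the negative class so annotation precision is
favoured over recall.

To avoid computing AHD from a test bag to every stored training bag, a
locality matrix is built once: training bags are clustered by k-medoids
under AHD, and row i of the s-by-K matrix lists the K training bags nearest
to medoid i.  At test time only medoid distances are computed; the rows of
the nearest medoids supply the candidate training bags for the vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mil_core import AHDCalculator, Bag, Standardizer

__all__ = [
    "CitationModel",
    "LocalityMatrix",
    "fit_citation",
    "predict_citation",
    "build_locality_matrix",
    "predict_citation_pruned",
    "kmedoids",
]

DEFAULT_K = 3  # reference rank; citer rank defaults to K + 2


@dataclass
class LocalityMatrix:
    medoid_ids: np.ndarray    # (s,) training-bag indices of cluster medoids
    rows: np.ndarray          # (s, K) training-bag indices, sorted by AHD to medoid

    @property
    def s(self) -> int:
        return self.medoid_ids.size

    @property
    def K(self) -> int:
        return self.rows.shape[1]


@dataclass
class CitationModel:
    """Stored training set + vote parameters for one annotation term."""

    term: str
    training_bags: list[Bag]
    labels: np.ndarray
    R: int
    C: int
    standardizer: Standardizer | None = None
    locality: LocalityMatrix | None = None
    calculator: AHDCalculator = field(default_factory=AHDCalculator)
    _train_dist: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.training_bags)

    def train_distances(self) -> np.ndarray:
        """Pairwise AHD among training bags (cached)."""
        if self._train_dist is None:
            self._train_dist = self.calculator.pairwise(
                self.training_bags, self.training_bags)
        return self._train_dist

    def test_distances(self, test: Bag) -> np.ndarray:
        if self.standardizer is not None:
            test = self.standardizer.transform(test)
        return np.array([self.calculator(b, test) for b in self.training_bags])


def fit_citation(bags: list[Bag], labels, R: int = DEFAULT_K,
                 C: int | None = None, term: str = "term",
                 standardize: bool = False) -> CitationModel:
    """Store the training set; Citation-KNN has no fitting step beyond that.

    ``R`` is the reference rank and ``C`` the citer rank (default R + 2,
    following the citers-use-a-larger-rank convention).
    """
    labels = np.asarray(labels, dtype=int)
    if C is None:
        C = R + 2
    if R < 1 or C < R:
        raise ValueError("require R >= 1 and C >= R")
    if len(bags) < R + 1:
        raise ValueError(f"need at least R+1={R + 1} training bags, got {len(bags)}")
    if labels.shape != (len(bags),):
        raise ValueError("labels must align with bags")
    if labels.min() == labels.max():
        raise ValueError("training set must contain both classes")
    std = None
    if standardize:
        std = Standardizer().fit(bags)
        bags = std.transform_all(bags)
    return CitationModel(term=term, training_bags=list(bags), labels=labels,
                         R=R, C=C, standardizer=std)


def _vote(model: CitationModel, test_dist: np.ndarray,
          candidates: np.ndarray) -> int:
    """Reference + citer vote restricted to ``candidates`` (training indices)."""
    labels = model.labels
    cand = np.asarray(candidates, dtype=int)
    d_test = test_dist[cand]

    r = min(model.R, cand.size)
    ref_order = cand[np.lexsort((cand, d_test))][:r]

    train_d = model.train_distances()
    cand_set = set(cand.tolist())
    citers = []
    for i in cand:
        # rank of the test bag among i's neighbours (other candidates + test)
        closer = sum(
            1 for j in cand
            if j != i and j in cand_set and train_d[i, j] < test_dist[i]
        )
        if closer < model.C:
            citers.append(i)
    votes = np.concatenate([labels[ref_order], labels[np.asarray(citers, dtype=int)]]) \
        if citers else labels[ref_order]
    pos = int(votes.sum())
    neg = votes.size - pos
    return 1 if pos > neg else 0


def predict_citation(model: CitationModel, test: Bag) -> int:
    """Naive Citation-KNN prediction using every stored training bag."""
    test_dist = model.test_distances(test)
    return _vote(model, test_dist, np.arange(model.n))


def kmedoids(dist: np.ndarray, s: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """Plain PAM-style k-medoids on a precomputed distance matrix.

    Alternates nearest-medoid assignment with per-cluster medoid updates
    until stable.  Medoids are actual data points, as required when only a
    pairwise distance (here AHD) and no mean object exists.
    """
    n = dist.shape[0]
    if not 1 <= s <= n:
        raise ValueError(f"number of clusters s={s} must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=s, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(s):
            members = np.nonzero(assign == c)[0]
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return medoids


def build_locality_matrix(model: CitationModel, s: int | None = None,
                          K: int | None = None, seed: int = 0) -> LocalityMatrix:
    """Cluster the training set and tabulate each medoid's K nearest bags.

    Built once before testing; the pairwise training AHD matrix dominates
    the cost at O(n^2) distance evaluations.
    """
    n = model.n
    if s is None:
        s = int(np.ceil(np.sqrt(n)))
    if K is None:
        K = min(25, n)
    if s > n:
        raise ValueError(f"s={s} exceeds the {n} training bags")
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must be in [1, {n}]")
    dist = model.train_distances()
    medoids = kmedoids(dist, s, seed=seed)
    rows = np.empty((s, K), dtype=int)
    idx = np.arange(n)
    for r, mid in enumerate(medoids):
        order = idx[np.lexsort((idx, dist[mid]))]
        rows[r] = order[:K]
    lm = LocalityMatrix(medoid_ids=np.asarray(medoids), rows=rows)
    model.locality = lm
    return lm


def predict_citation_pruned(model: CitationModel, test: Bag, q: float = 0.5) -> int:
    """Citation-KNN vote over the locality-matrix candidate set.

    Distances are computed to the s medoids only; the ceil(q*s) nearest
    medoids contribute their rows, whose union is the candidate training
    set.  With q = 1 and K = n the candidate set is the whole training set
    and the result equals :func:`predict_citation` exactly.
    """
    if model.locality is None:
        raise ValueError("locality matrix not built; call build_locality_matrix")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    lm = model.locality
    if model.standardizer is not None:
        test_std = model.standardizer.transform(test)
    else:
        test_std = test
    med_dist = np.array([
        model.calculator(model.training_bags[m], test_std) for m in lm.medoid_ids])
    n_keep = int(np.ceil(q * lm.s))
    keep_rows = np.lexsort((np.arange(lm.s), med_dist))[:n_keep]
    candidates = np.unique(lm.rows[keep_rows].ravel())
    test_dist = np.full(model.n, np.inf)
    for i in candidates:
        test_dist[i] = model.calculator(model.training_bags[i], test_std)
    return _vote(model, test_dist, candidates)
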