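"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written without reference to the package
internals: plain Python loops and a dense eigendecomposition, so that
agreement with the fast paths is meaningful.
"""

import numpy as np

MISSING = -1


def maf_brute(dosages):
    """Per-site MAF by explicit allele counting (nan if no calls)."""
    out = []
    for row in dosages:
        alt = tot = 0
        for d in row:
            if d != MISSING:
                alt += int(d)
                tot += 2
        if tot == 0:
            out.append(float("nan"))
        else:
            f = alt / tot
            out.append(min(f, 1.0 - f))
    return np.array(out)


def maf_filter_brute(dosages, threshold, min_call_rate):
    """Indices of sites a brute-force recount would keep."""
    keep = []
    n_acc = dosages.shape[1]
    mafs = maf_brute(dosages)
    for i, row in enumerate(dosages):
        called = sum(1 for d in row if d != MISSING)
        if called / n_acc < min_call_rate:
            continue
        if np.isnan(mafs[i]) or mafs[i] < threshold:
            continue
        keep.append(i)
    return keep


def pca_eig_oracle(centered, n_components):
    """PCA via dense eigendecomposition of the feature covariance.

    ``centered`` is (sites x accessions), already imputed and centered.
    Returns (loadings, evr, scores) with the same sign convention as the
    package: largest-|loading| entry positive, ties to the lowest index.
    """
    d = centered.T  # observations x features
    n = d.shape[0]
    cov = d.T @ d / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    evr = vals / vals.sum()
    loadings = vecs[:, :n_components].T.copy()
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1.0
    scores = loadings @ centered
    return loadings, evr[:n_components], scores


def impute_center_brute(dosages):
    """Mean-impute then center, by explicit loops."""
    x = dosages.astype(float).copy()
    for i, row in enumerate(dosages):
        called = [int(d) for d in row if d != MISSING]
        mean = sum(called) / len(called)
        for j, d in enumerate(row):
            x[i, j] = (mean if d == MISSING else float(d)) - mean
    return x


def complete_linkage_brute(points):
    """O(n^3) complete-linkage agglomeration over row-vector points.

    Returns the sorted list of merge heights (topology-free), which is
    what the implementation is compared against.
    """
    clusters = [[i] for i in range(len(points))]
    pts = np.asarray(points, dtype=float)

    def cdist(a, b):
        return max(
            float(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
            for i in a for j in b
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def nearest_neighbor_brute(score_columns, labels, query):
    """Closest label by scanning all columns; ties to the smaller label."""
    best = None
    for j, label in enumerate(labels):
        d = float(np.sqrt(((score_columns[:, j] - query) ** 2).sum()))
        if best is None or (d, label) < best:
            best = (d, label)
    return best[1], best[0]


def hudson_fst(geno_a, geno_b):
    """Hudson's FST estimator (ratio of sums) from two dosage matrices.

    ``geno_a``/``geno_b`` are (sites x accessions) dosage matrices of two
    populations (no missing calls). Returns (fst, standard_error) with
    the SE from a 50-block jackknife over sites.
    """
    na = 2 * geno_a.shape[1]
    nb = 2 * geno_b.shape[1]
    p1 = geno_a.sum(axis=1) / na
    p2 = geno_b.sum(axis=1) / nb
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)

    def ratio(mask):
        return num[mask].sum() / den[mask].sum()

    n_sites = len(num)
    fst = num.sum() / den.sum()
    n_blocks = 50
    edges = np.linspace(0, n_sites, n_blocks + 1, dtype=int)
    reps = []
    for b in range(n_blocks):
        mask = np.ones(n_sites, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        reps.append(ratio(mask))
    reps = np.array(reps)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((reps - reps.mean()) ** 2).sum()))
    return float(fst), se
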