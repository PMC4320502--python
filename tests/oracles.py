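"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with explicit Python loops and the plainest
possible arithmetic, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_nsc(X, sample_classes):
    """Loop-based nearest-shrunken-centroid statistics.

    X: genes x samples array; sample_classes: class label per column.
    Returns dict with classes, overall, centroids, s, s0, m_k, d.
    """
    X = np.asarray(X, dtype=float)
    n_genes, n = X.shape
    classes = []
    for c in sample_classes:
        if c not in classes:
            classes.append(c)
    K = len(classes)
    members = {c: [j for j in range(n) if sample_classes[j] == c] for c in classes}

    overall = np.array([sum(X[i]) / n for i in range(n_genes)])
    centroids = np.zeros((n_genes, K))
    for k, c in enumerate(classes):
        for i in range(n_genes):
            centroids[i, k] = sum(X[i, j] for j in members[c]) / len(members[c])

    s = np.zeros(n_genes)
    for i in range(n_genes):
        ss = 0.0
        for k, c in enumerate(classes):
            for j in members[c]:
                ss += (X[i, j] - centroids[i, k]) ** 2
        s[i] = math.sqrt(ss / (n - K))
    s0 = float(np.median(s))
    m_k = np.array([math.sqrt(1.0 / len(members[c]) - 1.0 / n) for c in classes])

    d = np.zeros((n_genes, K))
    for i in range(n_genes):
        for k in range(K):
            d[i, k] = (centroids[i, k] - overall[i]) / (m_k[k] * (s[i] + s0))
    return {
        "classes": classes,
        "overall": overall,
        "centroids": centroids,
        "s": s,
        "s0": s0,
        "m_k": m_k,
        "d": d,
    }


def naive_shrink(stats, delta):
    """Soft-threshold d and rebuild centroids, elementwise loops."""
    d = stats["d"]
    n_genes, K = d.shape
    d_shr = np.zeros_like(d)
    centroids = np.zeros_like(d)
    for i in range(n_genes):
        for k in range(K):
            mag = abs(d[i, k]) - delta
            d_shr[i, k] = math.copysign(max(mag, 0.0), d[i, k])
            centroids[i, k] = stats["overall"][i] + stats["m_k"][k] * (
                stats["s"][i] + stats["s0"]
            ) * d_shr[i, k]
    return d_shr, centroids


def naive_classify(x, centroids, s, s0, priors):
    """Discriminant scores and argmin class index, explicit loops."""
    n_genes, K = centroids.shape
    scores = []
    for k in range(K):
        total = 0.0
        for i in range(n_genes):
            total += (x[i] - centroids[i, k]) ** 2 / (s[i] + s0) ** 2
        scores.append(total - 2.0 * math.log(priors[k]))
    best = 0
    for k in range(1, K):
        if scores[k] < scores[best]:
            best = k
    return best, np.array(scores)


def naive_collapse(values, probe_ids, probe_to_gene):
    """Per-gene argmax-of-means with first-wins ties; returns (gene_ids, rows)."""
    values = np.asarray(values, dtype=float)
    best: dict[str, int] = {}
    order: list[str] = []
    for i, probe in enumerate(probe_ids):
        gene = probe_to_gene[probe]
        mean_i = sum(values[i]) / values.shape[1]
        if gene not in order:
            order.append(gene)
            best[gene] = i
        else:
            if mean_i > sum(values[best[gene]]) / values.shape[1]:
                best[gene] = i
    return order, values[[best[g] for g in order]]


def naive_scores(values, gene_ids, panels):
    """Per-sample loop over panel genes; returns classes x samples array."""
    values = np.asarray(values, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    out = []
    for genes in panels.values():
        present = [g for g in genes if g in index]
        col = []
        for j in range(values.shape[1]):
            col.append(sum(values[index[g], j] for g in present) / len(present))
        out.append(col)
    return np.array(out)


def naive_self_recovery(score_df, labels):
    """Per-class strict-max check by explicit grouping."""
    passed = {}
    for cls in score_df.columns:
        own = [score_df.loc[s, cls] for s in score_df.index if labels[s] == cls]
        other_means = []
        for other in {labels[s] for s in score_df.index} - {cls}:
            vals = [score_df.loc[s, cls] for s in score_df.index if labels[s] == other]
            other_means.append(sum(vals) / len(vals))
        passed[cls] = sum(own) / len(own) > max(other_means)
    return passed


def pooled_t(control, disease):
    """Closed-form pooled-variance t-test of disease - control: (t, df, p)."""
    from scipy import stats as sps

    n1, n2 = len(control), len(disease)
    m1 = sum(control) / n1
    m2 = sum(disease) / n2
    v1 = sum((x - m1) ** 2 for x in control) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in disease) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    t = (m2 - m1) / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p
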