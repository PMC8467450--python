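"""Independent oracles used to cross-check the implementation.

Everything here is deliberately naive — brute-force enumeration and
closed-form textbook formulas — and shares no code with the package's
inference or statistics paths.
"""

import itertools
import math

import numpy as np


def _normal_logpdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))


def enumeration_posterior(model, profile):
    """P(active | evidence) by summing the full joint over every latent
    configuration (pathway state × all gene transcription states).

    Log weights with a max-shift keep the naive sum from underflowing; the
    enumeration itself stays exhaustive.
    """
    genes = model.genes
    log_weights = {1: [], 0: []}
    for a in (0, 1):
        log_p_a = math.log(model.prior_active if a == 1 else 1.0 - model.prior_active)
        for tx in itertools.product((0, 1), repeat=len(genes)):
            lw = log_p_a
            for gene, t in zip(genes, tx):
                p_t1 = gene.p_tx_given_active if a == 1 else gene.p_tx_given_inactive
                p = p_t1 if t == 1 else (1.0 - p_t1)
                if p == 0.0:
                    lw = -math.inf
                    break
                lw += math.log(p)
                for ps in gene.probesets:
                    mu = ps.mu_high if t == 1 else ps.mu_low
                    lw += _normal_logpdf(profile[ps.probeset_id], mu, ps.sigma)
            log_weights[a].append(lw)
    shift = max(max(log_weights[1]), max(log_weights[0]))
    w1 = sum(math.exp(lw - shift) for lw in log_weights[1])
    w0 = sum(math.exp(lw - shift) for lw in log_weights[0])
    return w1 / (w1 + w0)


def anova_f(groups):
    """Between/within mean-square ratio from the textbook decomposition."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = sum(len(a) for a in arrays) - len(arrays)
    return (ss_between / df_between) / (ss_within / df_within)


def pearson_r(x, y):
    """Closed-form Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def random_small_model(rng, max_genes=4, max_probesets=2):
    """Random small pathway model for enumeration cross-checks."""
    from pathscore.sta_engine import (
        PathwayModel,
        ProbesetEmission,
        ScoreNormalization,
        TargetGene,
    )

    n_genes = int(rng.integers(1, max_genes + 1))
    genes = []
    for gi in range(n_genes):
        direction = "up" if rng.random() < 0.8 else "down"
        lo, hi = sorted(rng.uniform(0.02, 0.98, size=2))
        if hi - lo < 0.05:
            hi = min(0.99, lo + 0.05)
        p_a, p_i = (hi, lo) if direction == "up" else (lo, hi)
        n_ps = int(rng.integers(1, max_probesets + 1))
        probesets = []
        for pi in range(n_ps):
            mu_low = rng.uniform(3.0, 9.0)
            probesets.append(
                ProbesetEmission(
                    probeset_id=f"g{gi}_ps{pi}",
                    mu_low=mu_low,
                    mu_high=mu_low + rng.uniform(0.2, 4.0),
                    sigma=rng.uniform(0.1, 1.5),
                )
            )
        genes.append(
            TargetGene(
                symbol=f"G{gi}",
                direction=direction,
                p_tx_given_active=p_a,
                p_tx_given_inactive=p_i,
                probesets=tuple(probesets),
            )
        )
    return PathwayModel(
        pathway_name="toy",
        prior_active=float(rng.uniform(0.05, 0.95)),
        genes=tuple(genes),
        normalization=ScoreNormalization(-20.0, 20.0),
    )


def random_profile(model, rng):
    return {pid: float(rng.uniform(2.0, 12.0)) for pid in model.probeset_ids}
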