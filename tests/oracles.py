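"""Independent brute-force oracles shared by the unit and acceptance tests."""


def product_root_mean(scores):
    """Geometric mean by direct product and root; empty multiset -> 1."""
    if not scores:
        return 1.0
    product = 1.0
    for s in scores:
        product *= s
    return product ** (1.0 / len(scores))


def pairwise_concordance_auc(burdens, gs_drugs):
    """AUC as all-pairs concordance: P(GS drug below non-GS drug), ties 1/2.

    Lower burden means predicted positive, so a (gs, background) pair is
    concordant when the GS drug's burden is strictly smaller.
    """
    gs = [v for d, v in burdens.items() if d in gs_drugs]
    bg = [v for d, v in burdens.items() if d not in gs_drugs]
    total = 0.0
    for x in gs:
        for y in bg:
            if x < y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(gs) * len(bg))
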