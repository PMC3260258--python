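"""Independent brute-force oracles for cross-checking the inference path.

Everything here is deliberately naive pure-Python (explicit loops, exact
rational thresholds via Fraction) and shares no code with the package.
"""

from fractions import Fraction


def oracle_pair_consistency(reg, tgt, sign, delay=1):
    """Scalar re-implementation of transition-match counting."""
    total = 0
    matches = 0
    for i in range(len(reg) - delay):
        total += 1
        predicted = reg[i] if sign == "+" else 1 - reg[i]
        if tgt[i + delay] == predicted:
            matches += 1
    return Fraction(matches, total)


def oracle_infer(gene_ids, states, stringency_percent, conceptual=(), specific=(), delay=1):
    """Enumerate every ordered pair and transition with plain loops.

    Returns {(regulator, target): (sign, consistency Fraction)}.
    """
    threshold = Fraction(stringency_percent) / 100
    edges = {}
    for r, reg_gene in enumerate(gene_ids):
        if reg_gene in conceptual:
            continue
        for t, tgt_gene in enumerate(gene_ids):
            if r == t or (reg_gene, tgt_gene) in specific:
                continue
            c_act = oracle_pair_consistency(states[r], states[t], "+", delay)
            c_inh = oracle_pair_consistency(states[r], states[t], "-", delay)
            if c_act == c_inh:
                continue
            sign, best = ("+", c_act) if c_act > c_inh else ("-", c_inh)
            if best >= threshold:
                edges[(reg_gene, tgt_gene)] = (sign, best)
    return edges
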