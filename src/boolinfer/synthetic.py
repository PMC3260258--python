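"""Ground-truth generator: planted signed Boolean networks and noisy expression.

Benchmarking the inference pipeline needs datasets whose true network is
known.  The generator plants a random signed network with in-degree at most
one (so the single-regulator, one-step-delay inference model is exactly
identifiable), simulates the Boolean dynamics, and emits a continuous
expression matrix mimicking the short oscillatory microarray series the
method targets: 6-12 timepoints and peak-to-trough amplitudes around
1.3-3 log2 units.

Emission is two-level — baseline + amplitude/2 for an on state, baseline -
amplitude/2 for off, plus Gaussian noise — so that with zero noise the
dataset's measured amplitude equals the configured amplitude exactly and
every binarisation rule behaves analysably.  A fraction of genes is
designated "enzymatic" (out-degree zero), mirroring the conceptual
constraints of real analyses, and the generator returns a constraint set
built only from true non-relations so constraint-benefit experiments are
guaranteed fair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ACTIVATION, INHIBITION, LOG_RATIO, ExpressionMatrix
from .discretise import BinaryMatrix
from .infer import BooleanNetwork, ConstraintSet, SignedEdge

import pandas as pd


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic benchmark.

    Defaults mirror the circadian-clock-style test sets the method was
    designed around: 14 genes, 12 timepoints, amplitude 1.39 log2 units,
    with roughly 30% of genes enzymatic (4 of 14).
    """

    genes: int = 14
    timepoints: int = 12
    regulated_fraction: float = 0.6
    activation_fraction: float = 0.5
    amplitude: float = 1.39
    noise_sd: float = 0.25
    baseline: float = 0.0
    enzymatic_fraction: float = 0.3
    n_specific: int | None = None  # defaults to `genes` when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes < 2:
            raise ValueError("need at least 2 genes")
        if self.timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        for name in ("regulated_fraction", "activation_fraction", "enzymatic_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def _gene_names(k: int) -> list[str]:
    return [f"G{i:02d}" for i in range(k)]


def generate_truth(cfg: GeneratorConfig) -> tuple[BooleanNetwork, ConstraintSet]:
    """Plant a signed network (in-degree <= 1) and its true-non-edge constraints.

    Enzymatic genes (a seeded random subset of size
    round(enzymatic_fraction * k)) never regulate.  Each gene independently
    receives one regulator with probability ``regulated_fraction``, drawn
    uniformly from the non-enzymatic genes; the sign is activation with
    probability ``activation_fraction``.  The returned constraint set holds
    the enzymatic genes as conceptual constraints and a sample of
    ``n_specific`` true non-pairs as specific constraints, so applying it
    can never remove a planted edge.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.genes)
    n_enz = int(round(cfg.enzymatic_fraction * cfg.genes))
    if n_enz >= cfg.genes:
        n_enz = cfg.genes - 1  # at least one potential regulator
    enzymes = set(rng.choice(genes, size=n_enz, replace=False).tolist()) if n_enz else set()
    regulators = [g for g in genes if g not in enzymes]
    edges: list[SignedEdge] = []
    for tgt in genes:
        if rng.random() >= cfg.regulated_fraction:
            continue
        candidates = [g for g in regulators if g != tgt]
        if not candidates:
            continue
        reg = candidates[int(rng.integers(len(candidates)))]
        sign = ACTIVATION if rng.random() < cfg.activation_fraction else INHIBITION
        edges.append(SignedEdge(regulator=reg, target=tgt, sign=sign, consistency=1.0))
    truth = BooleanNetwork(
        genes=tuple(genes), edges=tuple(edges), provenance={"generator_seed": cfg.seed}
    )
    true_pairs = {(e.regulator, e.target) for e in edges}
    # informative specific constraints: true non-pairs not already barred
    # by the conceptual constraints
    candidates = [
        (r, t)
        for r in regulators
        for t in genes
        if r != t and (r, t) not in true_pairs
    ]
    n_spec = cfg.genes if cfg.n_specific is None else cfg.n_specific
    n_spec = min(n_spec, len(candidates))
    idx = rng.choice(len(candidates), size=n_spec, replace=False) if n_spec else []
    specific = frozenset(candidates[i] for i in idx)
    constraints = ConstraintSet(conceptual=frozenset(enzymes), specific=specific)
    return truth, constraints


def simulate_dynamics(net: BooleanNetwork, p: int, seed: int = 0) -> BinaryMatrix:
    """Run the one-step-delay Boolean dynamics for ``p`` timepoints.

    Unregulated genes get seeded random binary series; a regulated gene
    follows ``target[t+1] = reg[t]`` (activation) or its complement
    (inhibition), with a random initial state.  Genes with more than one
    regulator are rejected (the default generator never produces them).
    """
    if p < 3:
        raise ValueError("need at least 3 timepoints")
    regulator_of: dict[str, SignedEdge] = {}
    for e in net.edges:
        if e.target in regulator_of:
            raise ValueError(
                f"gene {e.target} has more than one regulator; "
                "single-regulator dynamics only"
            )
        regulator_of[e.target] = e
    rng = np.random.default_rng(seed)
    genes = list(net.genes)
    states = {g: np.zeros(p, dtype=np.int8) for g in genes}
    for g in genes:
        if g not in regulator_of:
            states[g][:] = rng.integers(0, 2, size=p)
        else:
            states[g][0] = rng.integers(0, 2)
    # cycles among regulated genes are fine: each state at t+1 depends only
    # on states at t, which are final once the previous step has run
    for t in range(p - 1):
        for g, e in regulator_of.items():
            src = states[e.regulator][t]
            states[g][t + 1] = src if e.sign == ACTIVATION else 1 - src
    mat = np.vstack([states[g] for g in genes])
    return BinaryMatrix(gene_ids=tuple(genes), states=mat, spec=None)


def emit_expression(
    states: BinaryMatrix, cfg: GeneratorConfig, seed: int | None = None
) -> ExpressionMatrix:
    """Map binary states to continuous log2-scale values with Gaussian noise.

    value = baseline + amplitude/2 (state 1) or baseline - amplitude/2
    (state 0), plus N(0, noise_sd).  With zero noise every non-constant
    profile has peak - trough exactly equal to the configured amplitude.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    half = cfg.amplitude / 2.0
    values = np.where(states.states == 1, cfg.baseline + half, cfg.baseline - half)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    df = pd.DataFrame(
        values,
        index=list(states.gene_ids),
        columns=[f"t{i}" for i in range(states.n_timepoints)],
    )
    return ExpressionMatrix(df, data_kind=LOG_RATIO)


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, BooleanNetwork, ConstraintSet, BinaryMatrix]:
    """One-call benchmark dataset: expression, truth, constraints, true states.

    Sub-seeds for topology, dynamics and noise are derived from ``cfg.seed``
    so distinct stages never share a random stream.
    """
    rng = np.random.default_rng(cfg.seed)
    s_truth, s_dyn, s_noise = (int(s) for s in rng.integers(0, 2**31 - 1, size=3))
    truth, constraints = generate_truth(replace(cfg, seed=s_truth))
    states = simulate_dynamics(truth, cfg.timepoints, seed=s_dyn)
    expr = emit_expression(states, cfg, seed=s_noise)
    return expr, truth, constraints, states
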