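"""Synthetic data generation with known ground truth.

Everything the analysis pipeline consumes can be generated here:
ultrametric pure-birth trees, continuous traits evolving under
Brownian-motion, Ornstein-Uhlenbeck, early-burst and multi-regime
models, binary habitat traits under a symmetric two-state Markov
process (or by thresholding a Brownian trait), within-species replicate
tables, amplitude-modulated tone-burst calling songs with known echeme
structure, and ecological tables with controlled inter-variable
correlation.

All generators are driven by integer seeds through
:class:`numpy.random.Generator`; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import PhyloTree, eb_transform

__all__ = [
    "SimulationSpec",
    "simulate_tree",
    "simulate_continuous",
    "simulate_binary",
    "threshold_binary",
    "simulate_individuals",
    "synthesize_song",
    "simulate_eco_table",
    "paper_shaped_spec",
]


@dataclass
class SimulationSpec:
    """Serializable description of one synthetic study.

    The defaults mirror the study design this package emulates: 14
    species on an ultrametric tree of height 1, a 9/5 arboreal/shrubby
    habitat split, log-scale acoustic traits with Brownian rates of the
    magnitude seen in cicada calling songs, and a handful of replicate
    individuals per species.
    """

    seed: int = 0
    n_tips: int = 14
    birth_rate: float = 1.0
    trait_model: str = "BM"
    trait_params: dict = field(default_factory=lambda: {"sigma2": 0.6, "z0": 2.0})
    within_sd: float = 0.15
    n_per_species: int = 5
    song: dict = field(default_factory=lambda: {
        "ne": 20, "ed": 0.030, "id": 0.010, "df": 12000.0,
        "sr": 44100, "noise_snr": None,
    })
    n_shrubby: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree, rescaled to total height 1.

    Speciation events occur at exponential waiting times with total
    rate ``birth_rate * k`` over ``k`` extant lineages; the process is
    stopped after the (n-1)-th split plus one final exponential stretch,
    then the whole tree is rescaled so every root-to-tip distance is 1.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)

    # Node bookkeeping in birth order; convert to PhyloTree at the end.
    parent_of: dict[int, int] = {}
    birth_time: dict[int, float] = {}
    nxt = 0

    root = nxt; nxt += 1
    birth_time[root] = 0.0
    t = 0.0
    active = []
    for _ in range(2):
        c = nxt; nxt += 1
        parent_of[c] = root
        birth_time[c] = 0.0
        active.append(c)
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        v = active[i]
        for _ in range(2):
            c = nxt; nxt += 1
            parent_of[c] = v
            birth_time[c] = t
            active.append(c)
        active.pop(i)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))

    n_total = nxt
    tips = sorted(active)
    internals = [v for v in range(n_total) if v not in set(tips) and v != root]
    order = tips + internals + [root]
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    end_time = {v: t_end for v in tips}
    # internal node's "end" is the birth time of its children
    child_birth: dict[int, float] = {}
    for c, p in parent_of.items():
        child_birth[p] = birth_time[c]
    for v in range(n_total):
        if v == root:
            continue
        p = parent_of[v]
        t1 = end_time.get(v, child_birth.get(v))
        parent[index[v]] = index[p]
        length[index[v]] = t1 - birth_time[v]
        children[index[p]].append(index[v])
    labels = [f"sp{i+1:02d}" for i in range(n_tips)]
    tree = PhyloTree(parent=parent, length=length, tip_labels=labels,
                     children=children)
    tree.length /= tree.height()
    return tree


# ---------------------------------------------------------------------------
# Traits


def _branch_regimes(tree: PhyloTree, regimes: Mapping[int, int] | Sequence[int]):
    r = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        r[v] = regimes[v]
    return r


def simulate_continuous(tree: PhyloTree, model: str, params: Mapping,
                        seed: int = 0, n_rep: int = 1,
                        regimes: Sequence[int] | None = None) -> np.ndarray:
    """Simulate a continuous trait branchwise along the tree.

    ``model`` is one of BM, OU, EB, BMS, OUMV.  Brownian increments are
    Normal(0, sigma2 * branch); OU uses the exact per-branch transition
    (mean reversion toward the branch's optimum theta at strength
    alpha).  Multi-regime models need ``regimes``: the regime index of
    the node at the tipward end of each branch (root entry = root
    regime).  Returns an ``(n_rep, n_tips)`` array (squeezed to 1-D when
    ``n_rep == 1``).
    """
    rng = np.random.default_rng(seed)
    model = model.upper()
    n = tree.n_tips
    x = np.zeros((n_rep, tree.n_nodes))

    if model == "EB":
        work = eb_transform(tree, float(params["r"]))
        bm_params = {"sigma2": params["sigma2"], "z0": params["z0"]}
        return simulate_continuous(work, "BM", bm_params, seed=seed, n_rep=n_rep)

    if model in ("BMS", "OUMV") and regimes is None:
        raise ValueError(f"{model} requires a regime painting")
    reg = _branch_regimes(tree, regimes) if regimes is not None else None

    if model == "BM":
        x[:, tree.root] = params["z0"]
    elif model == "BMS":
        x[:, tree.root] = params["theta"]
    elif model == "OU":
        x[:, tree.root] = params["theta"]
    elif model == "OUMV":
        x[:, tree.root] = np.asarray(params["theta"])[reg[tree.root]]
    else:
        raise ValueError(f"unknown model {model!r}")

    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        b = tree.length[v]
        if model == "BM":
            s2 = params["sigma2"]
            x[:, v] = x[:, p] + rng.normal(0.0, np.sqrt(s2 * b), size=n_rep)
        elif model == "BMS":
            s2 = np.asarray(params["sigma2"])[reg[v]]
            x[:, v] = x[:, p] + rng.normal(0.0, np.sqrt(s2 * b), size=n_rep)
        else:  # OU / OUMV exact transition
            if model == "OU":
                a, s2, th = params["alpha"], params["sigma2"], params["theta"]
            else:
                a = params["alpha"]
                s2 = np.asarray(params["sigma2"])[reg[v]]
                th = np.asarray(params["theta"])[reg[v]]
            w = np.exp(-a * b)
            var = s2 * (1.0 - np.exp(-2.0 * a * b)) / (2.0 * a) if a > 0 else s2 * b
            x[:, v] = th + (x[:, p] - th) * w + rng.normal(0.0, np.sqrt(var), n_rep)

    tipvals = x[:, :n]
    return tipvals[0] if n_rep == 1 else tipvals


def simulate_binary(tree: PhyloTree, mk_rate: float, seed: int = 0) -> np.ndarray:
    """Two-state symmetric Markov (Mk) simulation along branches.

    The root state is drawn from the stationary distribution (1/2, 1/2);
    along a branch of length t the probability of ending in the other
    state is (1 - exp(-2 q t)) / 2.
    """
    if mk_rate <= 0:
        raise ValueError("mk_rate must be positive")
    rng = np.random.default_rng(seed)
    state = np.zeros(tree.n_nodes, dtype=int)
    state[tree.root] = rng.integers(2)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * mk_rate * tree.length[v]))
        flip = rng.random() < p_flip
        state[v] = state[p] ^ int(flip)
    return state[: tree.n_tips].copy()


def threshold_binary(continuous: np.ndarray, prevalence: int) -> np.ndarray:
    """Assign state 1 to the ``prevalence`` largest values of a trait.

    Rank-thresholding a Brownian trait is the Brownian null used by the
    D statistic: it produces a binary trait with exactly the observed
    number of 1s while inheriting the trait's phylogenetic structure.
    """
    x = np.asarray(continuous, dtype=float)
    out = np.zeros(x.shape[-1], dtype=int)
    out[np.argsort(x)[-prevalence:]] = 1
    return out


def simulate_individuals(species_means: Mapping[str, float], within_sd: float,
                         n_per_species: int, seed: int = 0) -> pd.DataFrame:
    """Per-individual replicate values around each species mean.

    Individuals are Normal(species mean, within_sd^2) so the
    species-level standard error within_sd / sqrt(n) is recoverable by
    the aggregation step.
    """
    if n_per_species < 1:
        raise ValueError("need at least one individual per species")
    rng = np.random.default_rng(seed)
    rows = []
    for sp, m in species_means.items():
        vals = rng.normal(m, within_sd, size=n_per_species)
        for j, v in enumerate(vals):
            rows.append({"species": sp, "individual": f"{sp}_i{j+1}", "value": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Songs


def synthesize_song(ne: int, ed: float, id_: float, df: float, sr: int = 44100,
                    noise_snr: float | None = None, seed: int = 0,
                    pad: float = 0.0, ramp: float = 0.002) -> tuple[int, np.ndarray]:
    """Amplitude-modulated tone bursts emulating a cicada calling song.

    ``ne`` echemes, each a sinusoid at carrier ``df`` Hz of duration
    ``ed`` s with raised-cosine on/offsets of ``ramp`` s, separated by
    silences of ``id_`` s.  Optional white noise at ``noise_snr`` dB.
    Returns (sample_rate, samples); total core duration is
    ``ne*ed + (ne-1)*id_`` plus ``2*pad``.
    """
    if ed <= 0 or id_ <= 0:
        raise ValueError("echeme and interval durations must be positive")
    if df >= sr / 2:
        raise ValueError(f"carrier {df} Hz violates Nyquist at sample rate {sr}")
    rng = np.random.default_rng(seed)
    n_ed = int(round(ed * sr))
    n_id = int(round(id_ * sr))
    n_pad = int(round(pad * sr))
    n_ramp = max(1, min(int(round(ramp * sr)), n_ed // 4))

    env = np.ones(n_ed)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = up
    env[-n_ramp:] = up[::-1]

    total = 2 * n_pad + ne * n_ed + (ne - 1) * n_id
    y = np.zeros(total)
    for k in range(ne):
        start = n_pad + k * (n_ed + n_id)
        t = (start + np.arange(n_ed)) / sr
        y[start:start + n_ed] = env * np.sin(2 * np.pi * df * t)
    if noise_snr is not None:
        sig_pow = np.mean(y**2)
        noise_pow = sig_pow / (10 ** (noise_snr / 10.0))
        y = y + rng.normal(0.0, np.sqrt(noise_pow), size=total)
    return sr, y


# ---------------------------------------------------------------------------
# Ecology


def simulate_eco_table(target_correlation: np.ndarray, n_rows: int,
                       seed: int = 0, var_names: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Gaussian table with a specified inter-variable correlation.

    Draws standard normals and colours them with the Cholesky factor of
    the target correlation matrix (must be positive definite).
    """
    R = np.asarray(target_correlation, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("target correlation must be square")
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation is not positive definite") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_rows, R.shape[0]))
    X = Z @ L.T
    names = list(var_names) if var_names is not None else [
        f"v{i+1}" for i in range(R.shape[0])
    ]
    return pd.DataFrame(X, columns=names)


# ---------------------------------------------------------------------------
# Packaged study-shaped spec


def paper_shaped_spec(seed: int = 0) -> SimulationSpec:
    """The packaged default: a 14-species study-shaped synthetic setup."""
    return SimulationSpec(seed=seed)
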