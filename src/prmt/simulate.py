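"""Synthetic reaction catalogs, count tables, and parameter tables.

The generator emulates the shape of a seasonal marine metagenome study:
a few samples, a few hundred unique enzyme functions with sparse,
heavy-tailed (rounded log-normal) read counts, and a reaction catalog
in which most reactions are reversible. Defaults are 100 metabolites x
200 enzymes x 3 samples with 70% reversible reactions — a 3-time-point
design at roughly one tenth of the enzyme scale of a real coastal
time-series annotation.

Planted structure makes every downstream stage testable without any
external database:

* a *consume* signal multiplies, in one sample, the counts of every
  enzyme whose net connectivity consumes a target metabolite (a
  *produce* signal targets net producers), so the expected sign of the
  target's turnover score in that sample is known;
* a *parameter link* builds a measured series as 2**(slope * score +
  noise), so its log relative abundance correlates with the score
  series with known expected sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emm import build_connectivity
from .reactions import Reaction, ReactionCatalog, expand_directions

PATHWAY_POOL = ("map00010", "map00020", "map00051", "map00260", "map00520")


@dataclass(frozen=True)
class PlantedSignal:
    metabolite: str
    sample: str
    direction: str  # consume | produce
    fold: float = 8.0


@dataclass(frozen=True)
class ParameterLink:
    parameter_id: str
    metabolite: str
    slope: float = 1.0
    noise_sd: float = 0.1


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study; defaults are the standard conditions."""

    n_metabolites: int = 100
    n_enzymes: int = 200
    mean_reactions_per_enzyme: float = 2.0
    reversible_fraction: float = 0.7
    n_samples: int = 3
    count_log_mean: float = 3.0  # natural-log scale of per-enzyme baselines
    count_log_sd: float = 1.5  # heavy tail ACROSS enzymes
    sample_log_sd: float = 0.25  # between-sample wobble around the baseline
    sparsity: float = 0.3  # Bernoulli dropout probability per cell
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    parameter_links: list[ParameterLink] = field(default_factory=list)
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


def generate_catalog(spec: FixtureSpec) -> ReactionCatalog:
    """Random bipartite-style catalog, deterministic given the seed.

    Each enzyme catalyzes 1 + Poisson(mean-1) reactions; each reaction
    draws 1-2 substrates and 1-2 disjoint products and is reversible
    with probability ``reversible_fraction``.
    """
    if spec.n_metabolites < 2 or spec.n_enzymes < 1:
        raise ValueError("need >= 2 metabolites and >= 1 enzyme")
    if spec.n_metabolites < 4:
        # a reaction needs up to 2 substrates + 2 disjoint products
        raise ValueError("need >= 4 metabolites to draw disjoint reaction sides")
    rng = np.random.default_rng(spec.seed)
    metabolites = [f"C{i:04d}" for i in range(spec.n_metabolites)]
    reactions: list[Reaction] = []
    rid = 0
    for e in range(spec.n_enzymes):
        enzyme = f"{1 + e // 1000}.{1 + (e // 100) % 10}.{1 + (e // 10) % 10}.{e % 10 + 1}"
        n_rxn = 1 + rng.poisson(max(spec.mean_reactions_per_enzyme - 1.0, 0.0))
        for _ in range(n_rxn):
            picked = rng.choice(
                spec.n_metabolites, size=int(rng.integers(2, 5)), replace=False
            )
            n_subs = max(1, len(picked) // 2)
            subs = frozenset(metabolites[i] for i in picked[:n_subs])
            prods = frozenset(metabolites[i] for i in picked[n_subs:])
            rid += 1
            reactions.append(
                Reaction(
                    reaction_id=f"R{rid:05d}",
                    enzyme_id=enzyme,
                    substrates=subs,
                    products=prods,
                    reversible=bool(rng.random() < spec.reversible_fraction),
                    pathway_ids=frozenset({PATHWAY_POOL[rid % len(PATHWAY_POOL)]}),
                )
            )
    return ReactionCatalog(reactions)


def net_consumers_producers(
    catalog: ReactionCatalog, metabolite: str
) -> tuple[list[str], list[str]]:
    """Enzymes whose net connectivity consumes / produces a metabolite."""
    conn = build_connectivity(expand_directions(catalog))
    if metabolite not in conn.index:
        raise ValueError(f"metabolite {metabolite!r} not in catalog")
    row = conn.loc[metabolite]
    return list(row.index[row < 0]), list(row.index[row > 0])


def pick_plantable_metabolite(
    catalog: ReactionCatalog, direction: str = "consume", seed: int = 0
) -> str:
    """A metabolite with at least one net consumer (or producer).

    With mostly-reversible catalogs some metabolites have all-zero
    connectivity rows; planting a signal there would be unobservable by
    construction.
    """
    conn = build_connectivity(expand_directions(catalog))
    mask = (conn < 0).any(axis=1) if direction == "consume" else (conn > 0).any(axis=1)
    candidates = sorted(conn.index[mask])
    if not candidates:
        raise ValueError(f"no metabolite has a net {direction}r in this catalog")
    rng = np.random.default_rng(seed)
    return candidates[int(rng.integers(len(candidates)))]


def generate_counts(catalog: ReactionCatalog, spec: FixtureSpec) -> pd.DataFrame:
    """Sparse heavy-tailed count table with planted fold-changes applied.

    Abundance is heavy-tailed across enzymes (log-normal baseline per
    enzyme) but correlated across samples of the same community: each
    cell wobbles around its enzyme's baseline with a much smaller
    log-normal factor, plus Bernoulli dropout.
    """
    rng = np.random.default_rng(spec.seed + 1)
    enzymes = sorted(catalog.enzyme_universe)
    samples = spec.sample_ids
    baseline = rng.lognormal(spec.count_log_mean, spec.count_log_sd, size=len(enzymes))
    wobble = rng.lognormal(0.0, spec.sample_log_sd, size=(len(enzymes), len(samples)))
    keep = rng.random(wobble.shape) >= spec.sparsity
    counts = np.rint(baseline[:, None] * wobble * keep).astype(np.int64)
    df = pd.DataFrame(counts, index=enzymes, columns=samples)
    base = pd.Series(baseline, index=enzymes)
    wob = pd.DataFrame(wobble, index=enzymes, columns=samples)
    for signal in spec.planted_signals:
        if signal.direction not in ("consume", "produce"):
            raise ValueError(f"unknown planted direction {signal.direction!r}")
        consumers, producers = net_consumers_producers(catalog, signal.metabolite)
        targets = consumers if signal.direction == "consume" else producers
        if not targets:
            raise ValueError(
                f"planted metabolite {signal.metabolite!r} has no net "
                f"{signal.direction}r enzymes"
            )
        # the plant acts on the enzyme's underlying abundance, bypassing
        # dropout: otherwise a dropped-out cell would silently plant nothing
        # and the recorded truth would be false
        boosted = np.rint(base[targets] * wob.loc[targets, signal.sample] * signal.fold)
        df.loc[targets, signal.sample] = boosted.astype(np.int64)
    return df


def generate_parameters(prmt: pd.DataFrame, spec: FixtureSpec) -> pd.DataFrame:
    """Measured parameter series tied to score series with known sign.

    Each linked parameter is 2**(slope * score + N(0, noise_sd)) — a
    strictly positive series whose log relative abundance is, up to
    noise, an affine image of the target metabolite's score series.
    """
    rng = np.random.default_rng(spec.seed + 2)
    rows = {}
    for link in spec.parameter_links:
        if link.metabolite not in prmt.index:
            raise ValueError(f"linked metabolite {link.metabolite!r} has no scores")
        series = prmt.loc[link.metabolite].to_numpy(dtype=float)
        noise = rng.normal(0.0, link.noise_sd, size=series.size) if link.noise_sd > 0 else 0.0
        rows[link.parameter_id] = np.exp2(link.slope * series + noise)
    return pd.DataFrame(rows, index=prmt.columns).T


def manifest(spec: FixtureSpec) -> dict:
    """Planted truth as a plain dict (for TSV/JSON sidecars and tests)."""
    return {
        "seed": spec.seed,
        "n_metabolites": spec.n_metabolites,
        "n_enzymes": spec.n_enzymes,
        "n_samples": spec.n_samples,
        "reversible_fraction": spec.reversible_fraction,
        "planted_signals": [
            {
                "metabolite": s.metabolite,
                "sample": s.sample,
                "direction": s.direction,
                "fold": s.fold,
            }
            for s in spec.planted_signals
        ],
        "parameter_links": [
            {
                "parameter_id": l.parameter_id,
                "metabolite": l.metabolite,
                "slope": l.slope,
                "noise_sd": l.noise_sd,
            }
            for l in spec.parameter_links
        ],
    }
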