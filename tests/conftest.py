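import numpy as np
import pandas as pd
import pytest

from prmt import (
    FixtureSpec,
    Reaction,
    ReactionCatalog,
    build_connectivity,
    compute_eac,
    expand_directions,
    generate_catalog,
    generate_counts,
    normalize_emm,
    quantile_normalize,
    reference_neac,
)


def small_catalog(seed: int, max_reactions: int = 50) -> ReactionCatalog:
    """Random small catalog (<= max_reactions) for property tests."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        n_metabolites=int(rng.integers(4, 15)),
        n_enzymes=int(rng.integers(1, 12)),
        mean_reactions_per_enzyme=1.5,
        reversible_fraction=float(rng.random()),
        seed=seed,
    )
    catalog = generate_catalog(spec)
    return ReactionCatalog(catalog.reactions[:max_reactions])


def run_pipeline(catalog, counts, transform="log2p1", quantile=True):
    """Counts -> scores with the default reference (mean of nEACs)."""
    emm = normalize_emm(build_connectivity(expand_directions(catalog)))
    eac = compute_eac(counts, transform=transform)
    neac = quantile_normalize(eac) if quantile else eac
    from prmt import prmt_scores

    return prmt_scores(emm, neac, reference_neac(neac))


@pytest.fixture
def toy_catalog() -> ReactionCatalog:
    """Five-metabolite toy: one reversible, two irreversible reactions."""
    return ReactionCatalog(
        [
            Reaction("R1", "1.1.1.1", frozenset({"C1"}), frozenset({"C2"}), False,
                     frozenset({"map00010"})),
            Reaction("R2", "2.2.2.2", frozenset({"C2"}), frozenset({"C3"}), True,
                     frozenset({"map00020"})),
            Reaction("R3", "3.3.3.3", frozenset({"C3", "C4"}), frozenset({"C5"}),
                     False, frozenset({"map00010", "map00020"})),
        ]
    )


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"S1": [4, 2, 9], "S2": [1, 7, 3], "S3": [8, 0, 5]},
        index=["1.1.1.1", "2.2.2.2", "3.3.3.3"],
    )
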