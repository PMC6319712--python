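import numpy as np
import pandas as pd
import pytest

from evmir.quantify import CountMatrix


def make_count_matrix(counts: dict[str, list[int]], features: list[str] | None = None,
                      meta: dict[str, tuple[str, str, int]] | None = None) -> CountMatrix:
    """Build a CountMatrix from a dict of library -> counts.

    Library ids of the form "line-comp-Rk" get metadata parsed from the
    name unless ``meta`` overrides it.
    """
    df = pd.DataFrame(counts)
    df.index = features or [f"mir-{i}" for i in range(len(df))]
    rows = {}
    for lib in df.columns:
        if meta and lib in meta:
            line, comp, rep = meta[lib]
        else:
            parts = lib.rsplit("-", 2)
            line, comp, rep = parts[0], parts[1], int(parts[2].lstrip("R"))
        rows[lib] = {"cell_line": line, "compartment": comp, "replicate": rep}
    return CountMatrix(counts=df, libraries=pd.DataFrame.from_dict(rows, orient="index"))


@pytest.fixture
def two_group_matrix():
    """Four libraries, two groups, modest counts."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(3.0, 1.0, 50)
    counts = {f"x-{g}-R{r}": rng.poisson(mu).tolist()
              for g in ("A", "B") for r in (1, 2)}
    return make_count_matrix(counts)
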