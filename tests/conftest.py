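import numpy as np
import pandas as pd
import pytest

from cafepi.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A fast, fully default-structured configuration for unit tests."""
    return SimConfig(
        n_sites=200,
        coverage_mean=50,
        seed=7,
        n_fragments=150,
        n_samples_per_group=4,
        n_samples_expr=4,
    )


def make_estimates(rows):
    """Build a minimal estimate table for differential-call unit tests.

    rows: list of dicts with keys start, mc, hmc (and optionally coverage).
    """
    recs = []
    for r in rows:
        cov = r.get("coverage", 100)
        recs.append(
            {
                "chrom": "chrS",
                "start": r["start"],
                "u_bs": int(round((r["mc"] + r["hmc"]) * cov)),
                "c_bs": cov - int(round((r["mc"] + r["hmc"]) * cov)),
                "u_ox": int(round(r["mc"] * cov)),
                "c_ox": cov - int(round(r["mc"] * cov)),
                "testable": True,
                "mc": r["mc"],
                "hmc": r["hmc"],
            }
        )
    return pd.DataFrame(recs)
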