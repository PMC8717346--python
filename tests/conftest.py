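import numpy as np
import pandas as pd
import pytest

from songspace.io import ELEMENT_FEATURES


def make_element_df(n_songs=4, elements_per_song=3, seed=0, species="spA",
                    population="popA", features=ELEMENT_FEATURES):
    """Small hand-rolled element table with valid structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_songs):
        sex = "male" if s % 2 == 0 else "female"
        t = 0.0
        for e in range(elements_per_song):
            dur = 0.1 + 0.05 * rng.random()
            row = {
                "song_id": f"s{s}",
                "individual_id": f"i{s}",
                "population": population,
                "species": species,
                "sex": sex,
                "start_time": t,
                "end_time": t + dur,
            }
            for f in features:
                row[f] = rng.normal()
            row["freq_5"] = 2000 + 500 * rng.random()
            row["freq_95"] = row["freq_5"] + 1000 + 500 * rng.random()
            rows.append(row)
            t += dur + 0.05
    return pd.DataFrame(rows)


@pytest.fixture
def element_df():
    return make_element_df()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
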