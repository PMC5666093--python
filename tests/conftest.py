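import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def toy_encounters():
    """Four encounters, four whales, period P1; hand-countable dyad counts.

    For dyad (A, B): together in the same group once (E1), in different
    groups of the same encounter once (E2), and B is seen without A twice
    (E3, E4) — so SRI(A, B) = 1 / (1 + 1 + 0 + 2) = 0.25.
    """
    rows = [
        ("P1", "E1", "G1", "A"),
        ("P1", "E1", "G1", "B"),
        ("P1", "E1", "G2", "C"),
        ("P1", "E1", "G2", "D"),
        ("P1", "E2", "G1", "A"),
        ("P1", "E2", "G1", "C"),
        ("P1", "E2", "G2", "B"),
        ("P1", "E3", "G1", "B"),
        ("P1", "E3", "G1", "D"),
        ("P1", "E4", "G1", "B"),
        ("P1", "E4", "G1", "C"),
        ("P1", "E4", "G1", "D"),
    ]
    return pd.DataFrame(rows, columns=["period", "encounter", "group", "individual"])


@pytest.fixture
def toy_registry():
    return pd.DataFrame(
        {
            "id": ["A", "B", "C", "D"],
            "sex": ["M", "F", "U", "M"],
            "first_period": ["P1"] * 4,
            "last_period": ["P1"] * 4,
            "fate": ["censored"] * 4,
        }
    )


def brute_force_sri(encounters: pd.DataFrame, period: str, a: str, b: str) -> float:
    """Integer recount of the simple ratio index straight from the rows."""
    sub = encounters[encounters["period"].astype(str) == str(period)]
    x = y_ab = y_a = y_b = 0
    for _, enc in sub.groupby("encounter"):
        ga = set(enc.loc[enc["individual"] == a, "group"])
        gb = set(enc.loc[enc["individual"] == b, "group"])
        if ga and gb:
            if ga == gb:
                x += 1
            else:
                y_ab += 1
        elif ga:
            y_a += 1
        elif gb:
            y_b += 1
    denom = x + y_ab + y_a + y_b
    return x / denom if denom else 0.0


def random_encounter_table(rng: np.random.Generator, n_whales=None, n_encounters=None):
    """Random small grouped-sighting table (one group per whale per encounter)."""
    n_whales = n_whales or rng.integers(3, 11)
    n_encounters = n_encounters or rng.integers(2, 16)
    whales = [f"W{i}" for i in range(n_whales)]
    rows = []
    for e in range(n_encounters):
        present = [w for w in whales if rng.random() < 0.6]
        if not present:
            present = [whales[rng.integers(n_whales)]]
        n_groups = 1 + rng.integers(0, min(3, len(present)))
        assignment = rng.integers(0, n_groups, size=len(present))
        for w, g in zip(present, assignment):
            rows.append(("P1", f"E{e}", f"G{g}", w))
    return pd.DataFrame(rows, columns=["period", "encounter", "group", "individual"])
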