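import numpy as np
import pytest

from bcrisk import io as bio
from bcrisk.datatypes import PrsEntry, PrsModelDefinition, RateBand, RatesTable, VariantKey
from bcrisk.gail import load_gail_coefficients, packaged_data_path


@pytest.fixture(scope="session")
def coeffs():
    return load_gail_coefficients()


@pytest.fixture(scope="session")
def rates():
    return bio.read_rates_table(str(packaged_data_path("rates_illustrative.tsv")))


def flat_rates(incidence: float, mortality: float = 0.0) -> RatesTable:
    """Single-band [20,80) table with constant hazards (per person-year)."""
    return RatesTable(bands=(RateBand(20.0, 80.0, incidence, mortality),))


@pytest.fixture(scope="session")
def toy_panel():
    """3-variant panel: weights 0.1, -0.2, 0.05; one effect=ref site."""
    return PrsModelDefinition(
        entries=(
            PrsEntry(VariantKey("1", 100, "A", "G"), "G", 0.1, 0.25),
            PrsEntry(VariantKey("2", 200, "C", "T"), "T", -0.2, 0.5),
            PrsEntry(VariantKey("3", 300, "G", "A"), "G", 0.05, 0.8),  # effect = ref
        )
    )


def auc_by_pairs(scores, labels) -> float:
    """Brute-force Mann-Whitney concordance: ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def combined_auc_by_enumeration(clinical, genetic, carrier, labels) -> float:
    """Exhaustive threshold sweep over every pooled score value."""
    clinical = np.asarray(clinical, dtype=float)
    genetic = np.asarray(genetic, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for t in list(np.concatenate([clinical, genetic])) + [-np.inf, np.inf]:
        elev = (clinical >= t) | (genetic >= t) | carrier
        pts.add((float((elev & (labels == 0)).sum()) / n0,
                 float((elev & (labels == 1)).sum()) / n1))
    pts = np.array(sorted(pts))
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
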