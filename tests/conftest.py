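import numpy as np
import pandas as pd
import pytest

from tscreen.barcode_counting import CountMatrix


@pytest.fixture
def small_counts():
    """Tiny count matrix: 3 strains, 2 temperatures x 1 replicate x 2 times."""
    samples = pd.DataFrame(
        {
            "temperature": [30.0, 30.0, 42.0, 42.0],
            "time_h": [0.0, 12.0, 0.0, 12.0],
            "replicate": ["A", "A", "A", "A"],
        },
        index=pd.Index(["t30_0", "t30_12", "t42_0", "t42_12"], name="sample_id"),
    )
    counts = pd.DataFrame(
        {
            "t30_0": [100, 500, 400],
            "t30_12": [50, 550, 400],
            "t42_0": [100, 500, 400],
            "t42_12": [100, 500, 400],
        },
        index=pd.Index(["s1", "s2", "s3"], name="strain_id"),
    )
    return CountMatrix(counts, samples)


def planted_genome(rng, length, protospacer, offtarget=None):
    """Random genome with the protospacer+PAM planted once, optionally with
    a second (mutated) site; avoids accidental NGG 20-mers near-matching
    the protospacer by rejection."""
    bases = np.array(list("ACGT"))
    while True:
        g = "".join(rng.choice(bases, size=length))
        site = protospacer + "TGG"
        pos = int(rng.integers(50, length - 50 - len(site)))
        g = g[:pos] + site + g[pos + len(site):]
        if offtarget is not None:
            pos2 = int(rng.integers(50, length - 50 - len(site)))
            if abs(pos2 - pos) < 30:
                continue
            g = g[:pos2] + offtarget + "AGG" + g[pos2 + len(offtarget) + 3:]
        return g
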