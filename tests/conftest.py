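import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acetylome.io_tables import Protein, Proteome, SiteCatalog

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_proteome() -> Proteome:
    return Proteome([
        Protein("P1", "MKRAKSTYKAAC"),
        Protein("P2", "KSKYAAKKRLMK"),
        Protein("P3", "AAASTYAAA"),
    ])


@pytest.fixture
def tiny_catalog(tiny_proteome) -> SiteCatalog:
    rows = [
        ("P1", 2, "K", "acetyl", "leaf", "rep1", 2.0),
        ("P1", 2, "K", "acetyl", "leaf", "rep2", 6.0),
        ("P1", 2, "K", "acetyl", "root", "rep1", 1.0),
        ("P1", 5, "K", "acetyl", "leaf", "rep1", 6.0),
        ("P2", 1, "K", "acetyl", "root", "rep1", 3.0),
        ("P2", 3, "K", "acetyl", "root", "rep2", 1.0),
    ]
    frame = pd.DataFrame(rows, columns=[
        "protein_id", "position", "residue", "ptm_type", "organ",
        "replicate", "abundance"])
    return SiteCatalog.from_frame(frame, tiny_proteome, "tiny")
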