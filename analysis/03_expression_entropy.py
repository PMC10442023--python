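#!/usr/bin/env python
"""Expression-specificity contrast between acetylated and other genes.

Finds: over 158 samples the maximum Shannon entropy is log2(158) = 7.30
bits; acetylated genes (Dirichlet concentration 5) sit near that maximum
while non-acetylated genes (concentration 0.5) are far more sample-specific,
and the two-sided Mann-Whitney rank test separates the groups decisively.
The median-split hypergeometric test is reported alongside.  Table under
results/entropy/.
"""

import importlib
import math
import sys
from pathlib import Path

from acetylome import pipeline
from acetylome.io_tables import write_tsv

sys.path.insert(0, str(Path(__file__).parent))
sim = importlib.import_module("01_simulate")

OUT = Path("results/entropy")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    _, _, _, expr, _, _, kac_genes = sim.build_study()
    summary, tables = pipeline.stage_entropy(expr, kac_genes)
    write_tsv(tables["entropy_table"], OUT / "entropy_table.tsv")
    print(f"max entropy over {summary['n_samples']} samples: "
          f"{summary['max_entropy_bits']:.2f} bits")
    print(f"median entropy: acetylated {summary['median_kac']:.2f}, "
          f"other {summary['median_non']:.2f} bits "
          f"({summary['effect_direction']})")
    print(f"Mann-Whitney p = {summary['rank_test_p']:.3g}; "
          f"median-split hypergeometric p = {summary['hypergeom_p']:.3g}")
    print(f"table under {OUT}/")


if __name__ == "__main__":
    main()
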