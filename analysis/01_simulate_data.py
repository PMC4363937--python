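#!/usr/bin/env python
"""Generate the synthetic study bundle all downstream steps analyze.

Emulates the study design: a 3-vs-3 pooled two-group expression experiment
with a planted co-expression module around the index gene, a confidence-
scored interaction list with planted cliques and a designated hub, an
external co-expression gene list, and GMT annotations.  Ground truth goes
to truth.json so later steps can score recovery.
"""

from pathlib import Path

from coexnet.synthetic_data import write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    bundle = write_bundle(OUT, n_genes=600, n_cliques=8, seed=42)
    print(f"bundle written under {OUT}")
    print(f"  index gene: {bundle['index_gene']}  planted hub: {bundle['hub_gene']}")
    print(f"  planted pos module: {len(bundle['expr_truth'].pos_module)} genes")
    print(f"  planted cliques: {len(bundle['net_truth'].planted_cliques)}")


if __name__ == "__main__":
    main()
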