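"""Generate the synthetic study inputs.

Builds a toy multi-chromosome genome carrying a planted helicase-like
gene family (two tandem clusters of three plus two cross-chromosome
segmental pairs, with three decoy genes), promoters with planted
cis-element counts, and a replicate qPCR Ct table with planted fold
changes. Everything downstream runs off results/sim/.
"""

import sys
from pathlib import Path

from genefam.synthetic import (CtDesign, FamilyConfig, simulate_ct_table,
                               simulate_family, write_family)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    data = simulate_family(FamilyConfig(), seed=SEED)
    write_family(data, OUT)
    designs = [CtDesign("drought", ["100", "60", "30"], "100"),
               CtDesign("salt", ["0", "100", "200"], "0")]
    true_fc = {g: {tuple(c.split("/")): fc for c, fc in conds.items()}
               for g, conds in data.truth.expression_truth.items()}
    simulate_ct_table(designs, true_fc, seed=SEED).to_csv(OUT / "ct.csv", index=False)
    members = {g for p in data.truth.pair_truth for g in (p["gene_a"], p["gene_b"])}
    print(f"wrote {OUT}: {len(data.genes)} genes "
          f"({len(members)} family members, "
          f"{len(data.genes) - len(members)} decoys), "
          f"{len(data.truth.pair_truth)} true duplicate pairs, seed={SEED}")


if __name__ == "__main__":
    main()
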