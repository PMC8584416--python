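#!/usr/bin/env python
"""Free-living (FL) vs symbiotic nitrogen-fixing (SNF) state subnetworks.

Each state keeps a gene only when strictly more than 80% of its replicates
pass the 0.06 detection p-value cut; a PPI survives when both partners are
expressed. Three comparisons follow: (i) transcription-level differences
D_ij of interacting pairs vs the n^2 all-pairs control (one-sided rank-sum,
alpha=0.01), (ii) the same per COG category between states, and (iii) the
five local topology metrics between the two state subnetworks (two-sided
rank-sum). Writes results/states.json, state_cog_differences.tsv and
state_metric_comparison.tsv.
"""

import json
from pathlib import Path

from rhizonet import io, states as st, topology as topo

ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "results" / "run"


def main() -> None:
    net = io.read_network(RUN / "snf_network.tsv")
    ann = io.read_annotations(RUN / "annotations.tsv")
    subs, levels = {}, {}
    out = {}
    for state in ("FL", "SNF"):
        expr = io.read_expression(RUN / f"expression_{state}.tsv", state=state)
        present, lvl = st.expressed_genes(expr)
        sub = st.induce_state_subnetwork(net, present)
        subs[state], levels[state] = sub, lvl
        io.write_network(sub, RUN / f"subnetwork_{state}.tsv")
        res = st.compare_ppi_vs_control(sub, lvl)
        print(f"{state}: {len(present)} expressed genes -> subnetwork "
              f"{sub.n_nodes()} nodes / {sub.n_edges()} PPIs; "
              f"D median PPIs {res.median_ppi:.3f} vs control {res.median_control:.3f} "
              f"(n {res.n_ppi} vs {res.n_control}), one-sided p = {res.pvalue:.3g}")
        out[state] = {
            "n_expressed": len(present), "n_nodes": sub.n_nodes(),
            "n_edges": sub.n_edges(), "median_d_ppi": res.median_ppi,
            "median_d_control": res.median_control, "pvalue": res.pvalue,
            "n_control": res.n_control,
        }

    per_cog = st.per_cog_state_comparison(
        subs["FL"], subs["SNF"], levels["FL"], levels["SNF"], ann
    )
    per_cog.to_csv(ROOT / "results" / "state_cog_differences.tsv", sep="\t",
                   index=False, float_format="%.4g")
    sig = per_cog[per_cog["pvalue"] < 0.01]
    print(f"per-COG FL-vs-SNF comparison: {len(per_cog)} categories tested, "
          f"{len(sig)} significant at 0.01")

    cmp_metrics = topo.compare_state_metrics(
        topo.local_metrics(subs["FL"]), topo.local_metrics(subs["SNF"])
    )
    cmp_metrics.columns = ["metric", "median_fl", "median_snf", "pvalue"]
    cmp_metrics.to_csv(ROOT / "results" / "state_metric_comparison.tsv", sep="\t",
                       index=False, float_format="%.4g")
    print("state topology comparison (two-sided rank-sum):")
    for _, r in cmp_metrics.iterrows():
        print(f"  {r['metric']}: FL {r['median_fl']:.4g} vs SNF {r['median_snf']:.4g}"
              f"  p = {r['pvalue']:.3g}")

    (ROOT / "results" / "states.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
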