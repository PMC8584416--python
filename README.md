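# rhizonet

Computational reconstruction and dissection of a rhizobial protein
interactome. The package is built for systems-biology work on
*Bradyrhizobium*-like symbiotic nitrogen-fixing (SNF) bacteria, where
experimentally measured protein–protein interactions (PPIs) are scarce: it
predicts a genome-scale PPI network from evidence transfer, validates it
statistically, and mines it for symbiosis-related functional modules and
connector hubs.

The pipeline has four parts:

1. **Prediction.** Interolog transfer — two target proteins are predicted to
   interact when their orthologs interact in a reference species — plus a
   domain-based route: domain–domain interactions (DDIs) are inferred from
   experimental PPI corpora (association score = interacting fraction of
   co-carrying protein pairs, kept at > 0.5) and from structural DDI tables,
   combined as `(association ∩ structural) ∪ {association ≥ 1} ∪
   {structural > 2}`, then projected back onto the target proteome. Domain
   hits are filtered at score > 20, e-value < 1e-5, coverage > 0.9.
2. **Validation.** Per-edge functional similarity (Wang GO measure,
   best-match average), subcellular colocalization, and coexpression (PCC of
   log profiles) are compared against degree-preserving Maslov–Sneppen
   rewirings by one-sided Wilcoxon rank-sum tests.
3. **Topology and control.** Local metrics (degree, clustering, closeness,
   betweenness, path length), power-law degree-distribution fits — log-log
   regression and the discrete MLE γ̂ = 1 + n·[Σ ln(x_i/(x_min−½))]⁻¹ — and,
   for networks in the γ < 2 regime, a minimum dominating set (MDS, exact
   branch-and-bound) with Fisher COG enrichment of its members. Pairwise
   COG-category enrichment is quantified as Z_ij = (A_ij − ⟨Rnd_ij⟩)/σ_ij
   against the rewired ensemble.
4. **States and modules.** Expression-defined free-living (FL) and SNF
   subnetworks (a gene counts as expressed when > 80% of replicates have
   detection p ≤ 0.06), the normalized transcription difference
   D_ij = |s_i − s_j|/(s_i + s_j) of interacting pairs versus the n²
   all-pairs control, and a seed-based SNF core subnetwork clustered with
   Markov clustering (MCL); "Tie of Modules" (TOM) hubs outside the key
   modules that connect two or more of them are identified, and conserved
   modules are matched across species through an ortholog map.

Every input format has a reader (TSV/SIF/GraphML edge lists, HMMER
domtblout, OBO, annotation and expression TSVs, InParanoid-style group
tables), and a synthetic-data module generates all inputs with planted,
recoverable structure so the whole pipeline is testable offline.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_predict_interactome.py
python analysis/03_validate_network.py
python analysis/04_topology_controllability.py
python analysis/05_cog_enrichment.py
python analysis/06_state_subnetworks.py
python analysis/07_snf_modules.py
```

Output of the prediction and dissection stages:

```
interolog: 756 edges from 2 reference species; planted-edge recall 1.000
domain route: 15 association DDIs, 10 after combination, 1020 predicted PPIs
global network: 279 proteins, 1759 PPIs, 1 components, 7 self-interactions
...
coexpression vs nulls: median PCC 0.750 vs null 0.037, one-sided p = 4.42e-25
...
FL: 42 expressed genes -> subnetwork 35 nodes / 104 PPIs; D median PPIs 0.170
    vs control 0.253 (n 104 vs 1225), one-sided p = 9.68e-06
...
SCSNW: 50 proteins / 70 PPIs from 6 seed proteins
key modules (planted): [1, 2, 3]; TOMs identified: ['bll0233', 'bll0257']
    (planted: ['bll0233', 'bll0257'])
```

Reading: interolog transfer recovered exactly the planted transferable edge
set; interacting pairs are far more coexpressed than degree-matched random
pairs (median PCC 0.75 vs 0.04); in both physiological states interacting
pairs have more similar transcription levels than the all-pairs control
(lower median D); and both planted connector hubs were recovered as TOMs
from the seed-extracted core subnetwork.

The same stages are available as a CLI over a run directory
(`rhizonet --seed 1 simulate --out run/`, then `rhizonet predict-interolog
--dir run/`, `... assemble`, `... topology`, `... snf-modules`, each writing
a provenance JSON with input hashes and parameters).

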