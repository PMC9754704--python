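# nupdi

Quantification of **nucleoporin detachment** from the nuclear envelope in
live-cell fluorescence microscopy, event-timing analysis of meiotic nuclear
pore complex (NPC) remodeling, the accompanying nonparametric statistics, and
a post-search processing chain for DIA (SWATH-type) phosphoproteomics — with
synthetic-data generators that make every stage testable against known ground
truth.

## Who this is for

During budding-yeast meiosis I, the nuclear-basket nucleoporins Nup60 and
Nup2 transiently leave the NPC and relocalize to the nucleoplasm, returning
to the nuclear periphery about ten minutes later; the event is driven by
Polo-kinase (Cdc5) phosphorylation. This package reimplements the
quantitative machinery needed to study that kind of remodeling event:
image-based partition quantification, event calling against cell-cycle
anchors, group statistics, and differential phosphorylation scoring from
precursor-level intensity matrices.

## The detachment index

For a tagged nucleoporin, the **detachment index (DI)** of one nucleus at one
timepoint is

```
DI = mean nucleoplasmic intensity / mean nuclear-envelope intensity
```

measured on a single mid-nucleus z-slice after rolling-ball background
subtraction. DI is a scale-free ratio: near 0 for a fully peripheral protein,
rising toward (and past) 1 as the protein detaches. Two independent methods
are implemented:

* **mask method** (`imaging_quant`) — a nuclear mask from the histone
  channel is eroded to give the nucleoplasmic mask and dilated to bound the
  envelope annulus; the envelope signal is the total nuclear signal minus
  the nucleoplasmic signal.
* **line-profile method** (`line_profile`) — a five-pixel-wide intensity
  profile across the nucleus shows the envelope as two peaks; DI is the mean
  of the middle 50% of the inter-peak span divided by the mean peak height.

Detachment/reattachment timing (`event_timing`) operationalizes "near-maximal
relocalization" as the DI series crossing
`baseline + 0.8 * (peak - baseline)`, with anaphase onset (histone-mass
circularity drop or split) and SPB separation (two resolvable puncta) as
anchors. Group comparisons use Dunn's test against a reference group,
Wilcoxon signed-rank, and Wilcoxon rank-sum (`group_stats`).

The phosphoproteomics chain (`phospho_pipeline`) takes a precursor × sample
log2-intensity matrix through mean-centering, a 2-of-3 replicate filter,
two-branch left-censored imputation, protein summation, phosphosite
merging/splitting, and empirical-Bayes moderated t statistics with
Benjamini–Hochberg FDR for kinase-active vs. kinase-dead contrasts.

## Worked example

Simulate a small two-channel time-lapse, quantify DI, and call events:

```sh
nupdi simulate-images --out-dir demo --n-cells 2 --n-frames 8 --seed 0
nupdi quantify --stack demo/stack.tiff --crops demo/crops.csv \
    --out demo/di.csv --method mask
python -c "import pandas as pd; df = pd.read_csv('demo/di.csv'); \
    df[['cell_id','t_min','di']].dropna().to_csv('demo/tidy.csv', index=False)"
nupdi events --di-csv demo/tidy.csv --out-dir demo/events
```

Each simulated cell detaches at a programmed frame (cells 0 and 1 at 15 and
20 min) and reattaches 10 min later. The event caller returns, in
`demo/events/event_calls.csv`:

```
cell_id,t_detach,t_reattach,duration,replicate,qc_flags
cell00,15,25,10,,
cell01,20,30,10,,
```

i.e. both programmed detachment times and the 10-minute durations are
recovered exactly on the 5-minute acquisition grid.

The phospho side, from the library:

```python
from nupdi import (PhosphoSimConfig, simulate_precursor_table,
                   log2_and_center, filter_by_replication, impute_missing,
                   merge_sites, differential_phospho)

table, truth = simulate_precursor_table(
    PhosphoSimConfig(n_proteins=500, n_planted=25, planted_log2fc=2.0,
                     noise_sd=0.5, seed=14))
filtered, dropped = filter_by_replication(log2_and_center(table))
sites = merge_sites(impute_missing(filtered, seed=14))
res = differential_phospho(sites)
print(res["significant"].sum())
```

which recovers the planted differential sites at BH 0.05 (see
`tests/test_acceptance.py` for the quantitative power check).

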