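# refugia

Statistical phylogeography of glacial-refugium lineages: a Python library
for testing how arctic–alpine plant populations diverged among refugia
through Pleistocene glacial cycles.  It was built around a five-region,
46-specimen trans-Beringian sampling design (North America Interior, North
America Cascadia, Beringia, Central Asia & Siberia, Japan) but every stage
is parameterised and works on arbitrary regions, trees and characters.

Three inference procedures are provided:

1. **Coalescent tests of divergence models** (`refugia.divergence`,
   `refugia.coalsim`, `refugia.deepcoal`).  Competing biogeographic
   hypotheses (simultaneous fragmentation among all refugia; stepwise
   westward/eastward dispersal chains) are encoded as population trees.
   The deep-coalescence statistic *DC* counts, under the LCA mapping, the
   minimal number of extra gene lineages needed to reconcile an observed
   gene tree with a population tree — discordance attributed to incomplete
   lineage sorting.  A null distribution of DC is built by simulating gene
   trees within each model under the multispecies coalescent (pairwise
   coalescence rate k(k−1)/2 per 2Nₑ generations), and a model is
   *supported* when the observed DC falls in the lower tail,
   p = (1 + #{DC_null ≤ DC_obs}) / (1 + n_sims) < α.

2. **Time-stratified DEC maximum likelihood** (`refugia.dec`).  Geographic
   ranges are area sets evolving by anagenetic dispersal (rate *d*,
   modulated by a per-stratum dispersal matrix) and extinction (rate *e*),
   with cladogenetic range inheritance from the classic
   dispersal–extinction–cladogenesis scenario set (sympatric inheritance of
   singletons, single-area vicariance, subset sympatry).  Strata model
   glacial cycles: dispersal between adjacent areas is possible only during
   interglacials (240–190, 130–90, 10–0 ky before present) and blocked
   during glacials.  The likelihood is computed by postorder pruning with
   per-segment matrix exponentials; `fit_dec` profiles (d, e) by bounded
   multistart ML and reports per-root-range constrained likelihoods and a
   two-log-likelihood-unit comparison window across models.

3. **Prior-calibrated ancestral-state reconstruction** (`refugia.asr`).
   Binary morphological characters evolve under a two-state CTMC whose
   overall rate carries a gamma(α, β) prior estimated per character by MCMC
   over a posterior tree sample.  The marginal posterior of the state at a
   named clade's MRCA is computed exactly by the pruning (up–down)
   algorithm for each tree × prior draw and averaged; calls above 0.95 are
   flagged significant and re-checked under 0.1× and 10× prior-mean scaling.

A synthetic-data module (`refugia.synthetic`) generates all inputs — a
coalescent gene tree scaled to a 220-ky root age, DEC-evolved ranges,
sixteen binary characters, a posterior-like tree sample — with a manifest
of seeds and true parameters, so the full pipeline runs and is testable
with no external data.

## Worked example

```bash
python examples/01_coalescent_dc_test.py
```

simulates an observed gene tree under a strongly sorted westward-dispersal
(SRM) history and tests all six divergence models against it:

```
   model  observed_dc  null_mean  null_sd  p_value  decision
 REFUGIA            0     2.3700   1.3187 0.065467  rejected
     SRM            2     8.4665   2.7926 0.012494 supported
 JAPAN_I            6     9.1035   2.9396 0.182909  rejected
JAPAN_II            6     9.3480   2.8962 0.163418  rejected
   CAS_I            4     9.0905   2.8318 0.047476 supported
  CAS_II            4     9.1300   2.8921 0.044978 supported
```

The generating scenario keeps the observed DC tiny (2 extra lineages)
against a null centred near 8.5, so it is supported at α = 0.05; a
topologically mismatched origin in Japan pays six extra lineages and is
rejected.  The other examples fit the stratified DEC models
(`02_stratified_dec_fits.py`, the generating SRM model ranks best and the
refugial no-dispersal model falls far outside the 2-lnL window) and run the
prior-calibrated ASR with its sensitivity scan (`03_character_asr.py`).

A thin CLI wraps the same calls:

```bash
refugia simulate --out bundle/ --seed 1
refugia dctest --bundle bundle/ --seed 1 --out reports/
refugia dec    --bundle bundle/ --seed 1 --out reports/
refugia asr    --bundle bundle/ --seed 1 --out reports/
```

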