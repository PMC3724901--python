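"""Prior-calibrated ancestral-state reconstruction of binary characters.

Estimates a gamma rate prior for one morphological character by MCMC over
a posterior-like tree sample, reconstructs the character state at a named
clade's ancestor, and checks the call's robustness to 0.1x/10x prior-mean
scaling.  A state is called significant when its posterior exceeds 0.95.
"""

from refugia import asr, synthetic

bundle = synthetic.generate_fixture(seed=1)
char = bundle.characters[0]  # growth habit: dense vs loose mats
clade = bundle.clades["NAI"]

prior = asr.estimate_rate_prior(char, bundle.tree_sample, n_iter=400,
                                burnin=100, seed=3)
print(f"character {char.name!r}: gamma prior alpha={prior.alpha:.3f} "
      f"beta={prior.beta:.3f} (mean rate {prior.mean:.2f}/tree depth)")

scan = asr.sensitivity_scan(char, bundle.tree_sample, prior, clade,
                            factors=(0.1, 1.0, 10.0), n_draws=20, seed=3,
                            clade_id="NAI")
print(scan.to_string(index=False))
print(
    "\np_<state> columns are posterior probabilities of each state at the\n"
    "clade ancestor, averaged over trees and prior draws; calls_stable says\n"
    "whether the significance call survives the prior-mean scan."
)
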