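"""Generate a small synthetic EMR cohort and look at what was planted.

The generator plants healthcare-associated bloodstream infections at a
configurable rate (default 14.7 episodes per 1000 patients) alongside the
near-miss negatives the detection rules must reject: community-onset
cultures, single-draw commensal contaminants, fevers without antimicrobial
response, and post-recall report revisions.
"""

from habsi import CohortConfig, generate

config = CohortConfig(n_patients=2000, seed=7)
bundle, labels = generate(config)

n_pos = int(labels.habsi.sum())
print(f"patients:          {config.n_patients}")
print(f"stays:             {len(bundle.stays)}")
print(f"blood cultures:    {sum(1 for c in bundle.cultures if c.specimen_type.value == 'blood')}")
print(f"vital-sign rows:   {len(bundle.vitals)}")
print(f"planted HABSI:     {n_pos}  ({1000 * n_pos / config.n_patients:.1f} per 1000 patients)")
print("planted subtype mix:")
print(labels[labels.habsi == 1].classification.value_counts().to_string())
# The subtype mix follows the configured probabilities; every planted case
# satisfies the detection rules by construction, every negative does not.
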