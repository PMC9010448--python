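"""Assess follow-up compound suggestions against a fragment-hit cohort.

Computes descriptors and rule-of-5 compliance for a small set of follow-ups
and quantifies the descriptor drift from the original hits — elaborated
compounds typically rise in every count along with molecular weight.
"""

from fragchal import (cohort_compare, compute_descriptors, morgan_fingerprint,
                      pairwise_tanimoto_summary, parse_smiles, rule_of_five)

hits = [parse_smiles(s, f"H{k}") for k, s in enumerate(
    ["c1ccc(O)cc1", "Cc1ccncc1", "NC(=O)c1ccoc1"])]
followups = [parse_smiles(s, f"S{k}") for k, s in enumerate(
    ["OCCc1ccc(O)cc1", "CCNC(=O)c1ccncc1", "NC(=O)c1ccoc1-c1ccccc1"])]

hit_desc = [compute_descriptors(m) for m in hits]
fu_desc = [compute_descriptors(m) for m in followups]
for m, d in zip(followups, fu_desc):
    ok, violations = rule_of_five(d)
    print(f"{m.id}: MW {d.molecular_weight:.1f}, logP {d.logp:.2f}, "
          f"HBD {d.hbd}, HBA {d.hba}, rule-of-5 "
          f"{'compliant' if ok else 'violations: ' + '; '.join(violations)}")

table = cohort_compare(hit_desc, fu_desc)
print("\nmean descriptor shift, follow-ups minus hits:")
print(table["diff_mean"].round(2).to_string())
# positive shifts: the follow-ups are larger/more feature-rich than the hits

fps = [morgan_fingerprint(m) for m in followups]
t = pairwise_tanimoto_summary(fps)
print(f"\nfollow-up pairwise Tanimoto: mean {t['mean']:.2f} over "
      f"{t['n_pairs']} pairs (1 = identical fingerprints)")
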