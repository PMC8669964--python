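"""Turn a compact gene panel into human-readable IF-THEN decision rules.

A CART tree is grown on all samples of the panel; every root-to-leaf path
becomes one rule, and rules are summarized per class (rule count, criterion
count, distinct genes) - the standard panel-description table.
"""

from panel_ifs import (
    SyntheticSpec, extract_rules, generate_dataset, rank_mrmr,
    summarize_rules, train_tree,
)

spec = SyntheticSpec(n_classes=3, class_sizes=[50, 35, 20],
                     n_informative=8, n_noise=92, seed=17)
dataset, _ = generate_dataset(spec)
panel = rank_mrmr(dataset, n_select=10).gene_ids

model = train_tree(dataset, panel, seed=0)
rules = extract_rules(model)

print(f"{len(rules.rules)} rules from a tree with {model.n_leaves} leaves\n")
for i, rule in enumerate(rules.rules[:4], start=1):
    conds = " AND ".join(f"{g} {op} {thr:.2f}" for g, op, thr in rule.criteria)
    print(f"Rule {i}: IF {conds}\n        THEN {rule.class_name} "
          f"(support {rule.support})")
print("...\nper-class summary:")
print(summarize_rules(rules))
# Support is the number of training samples satisfying the rule; the
# summary mirrors how rule sets are reported for tumor-type panels.
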