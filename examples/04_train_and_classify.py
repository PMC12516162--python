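"""Train the joint lesion/PRL/CVS network on phantoms and classify held-out
candidates.

A deliberately small run (4 training + 2 held-out subjects, narrow network,
few epochs) so it finishes in a few minutes on one CPU; the candidate-level
AUROCs it prints improve with more subjects and epochs (see
scripts/acceptance.py for the full desk-scale experiment).
"""

import rimvein as rv

spec = rv.PhantomSpec(volume_shape=(48, 48, 48), n_lesions=6, n_prl=2,
                      n_cvs=2, n_confluent_pairs=1, seed=0)
net = rv.NetworkConfig(width_scale=1 / 32, seed=0)
cfg = rv.TrainConfig(pretrain_epochs=2, joint_epochs=5,
                     patches_per_subject=20, minibatch=16, seed=0)

result = rv.run_recovery_experiment(n_train=4, n_test=2, base_spec=spec,
                                    net_config=net, train_config=cfg, seed=0,
                                    n_eval_patches=15)

print("pretrain loss per epoch:", [round(x, 3) for x in result["pretrain_history"]])
print("joint loss per epoch:   ", [round(x, 3) for x in result["joint_history"]])
cols = ["subject", "candidate_id", "p_lesion", "p_prl", "p_cvs",
        "y_lesion", "y_prl", "y_cvs"]
print(result["candidates"][cols].round(3).to_string(index=False))
for k in ("lesion_auroc", "prl_auroc", "cvs_auroc", "coverage_pct"):
    print(f"{k}: {result[k]:.3f}")
print("\nEach held-out candidate gets three probabilities (lesion, PRL, CVS);"
      " y_* are the phantom ground-truth statuses; the AUROCs summarize how"
      " well the ensemble predictions rank true biomarkers above negatives.")
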