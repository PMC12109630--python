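"""Train a scaled GlandNet on two synthetic biopsies, evaluate on a third.

Uses the desk-scale network (width 1/8, 64-px patches) and prints the
eight-statistic ledger: the positive class is the glandular cell, so
sensitivity is the gland detection rate and specificity the stroma
recognition rate.
"""

from glandcell import SceneSpec, TrainConfig, build_biopsy_container, render_scene
from glandcell.classifier import build_model, classify, predict_proba, train
from glandcell.experiments import desk_model_spec
from glandcell.metrics import evaluate

containers = []
for i in range(3):
    scene = render_scene(SceneSpec(seed=20 + i))
    cont = build_biopsy_container(scene.image, scene.nuclei, scene.glands, 64, f"biopsy-{i}")
    for rec in cont.records:
        rec.label = scene.labels[rec.nucleus_id]
    containers.append(cont)

model = build_model(desk_model_spec(), seed=0)
print(f"model: {model.n_weight_layers} weight layers, {model.n_params:,} parameters")

history = train(model, containers[:2], TrainConfig.desk_scale(seed=0))
print(f"trained {len(history['loss'])} epochs; "
      f"final training accuracy {history['accuracy'][-1]:.2f}")

test = containers[2]
probs = predict_proba(model, test)
rep = evaluate([r.label for r in test.records], classify(probs, 0.5), probs)
print("held-out biopsy:", rep.rounded())
print("accuracy/sensitivity/specificity are percentages; "
      "auc/ap are areas under the ROC and precision-recall curves")
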