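"""Zero-shot image-to-image classification and linear probing on the full
desk-scale benchmark.

Runs the complete pipeline (generate -> train -> evaluate all protocols);
expect a few minutes on one CPU core.
"""

from cellmol.workflows import BenchmarkConfig, run_benchmark

result = run_benchmark(BenchmarkConfig(seed=1))

ret = result.retrieval
print(f"retrieval among {ret['n_candidates']} held-out molecules "
      f"(chance {ret['chance_top1_percent']:.1f}%):")
print(f"  structure retrieval top-1 {ret['structure_top1_percent']:.1f}% "
      f"({ret['structure_lift']:.0f}x chance)")
print(f"  image retrieval     top-1 {ret['image_top1_percent']:.1f}% "
      f"({ret['image_lift']:.0f}x chance)")

zs = result.zeroshot
print(f"zero-shot molecule classification, {zs['n_classes']} unseen classes, "
      f"{zs['n_queries']} queries:")
print(f"  top-1 {zs['top1_percent']:.1f}% ({zs['lift']:.0f}x chance), "
      f"top-5 {zs['top5_percent']:.1f}%")

pr = result.probe
print(f"linear probe on frozen penultimate features, {pr['n_scored']} tasks:")
print(f"  mean AUC {pr['mean_auc']:.3f} "
      f"(tasks > 0.9: {pr['auc_above'][0.9]}, > 0.8: {pr['auc_above'][0.8]})")
print(f"  shuffled-label control AUC {pr['shuffled_mean_auc']:.3f} "
      "(chance ~ 0.5: the signal is in the features, not the harness)")
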