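"""Detect a planted clone in a synthetic western-blot figure.

Builds a one-panel blot phantom with a mirrored 48x48 duplication,
runs the two-branch copy-move detector and scores the result against
the generator's ground-truth mask.
"""

from scifig.copymove import detect_copy_move
from scifig.metrics import iou, pixel_f1
from scifig.synthetic import make_clone_figure
from scifig.types import CopyMoveConfig

figure, truth = make_clone_figure(seed=0, kind="mirror")
report = detect_copy_move(figure, CopyMoveConfig())

print(f"figure {figure.id}: {figure.image.rows}x{figure.image.cols}")
print(f"  Zernike branch pixels: {int(report.zernike_mask.sum())}")
print(f"  RGB branch pixels:     {int(report.rgb_mask.sum())}")
print(f"  fused mask pixels:     {int(report.final_mask.sum())}")
print(f"  pixel F1 vs truth:     {pixel_f1(report.final_mask, truth):.3f}")
print(f"  IoU vs truth:          {iou(report.final_mask, truth):.3f}")
# A mirrored clone is caught by the rotation/mirror-invariant Zernike
# branch; raw-RGB features cannot match a flipped block, so the RGB
# branch stays near-empty.  F1 well above 0.5 means both the source
# band region and its mirrored copy were localized.
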