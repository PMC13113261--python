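"""Regenerate the builtin pair-registry JSON assets.

The dense-225 registry is a synthetic symmetric layout (the original
study's mesh index assignment is unpublished); the sparse registries use
the canonical 68-point left/right correspondence. Output is byte-stable.
"""
import json, pathlib

out = pathlib.Path(__file__).resolve().parents[1] / "src" / "facesym" / "registries"

# ---- dense-225: synthetic symmetric 478-point layout ----
# indices 0..19 midline, 20..27 mouth-axis points (excluded from midline fit),
# pair ordinal i -> (28+2i, 29+2i)
regions = ["eye"] * 40 + ["nose"] * 40 + ["mouth"] * 70 + ["other"] * 75
pairs = [{"left": 28 + 2 * i, "right": 29 + 2 * i, "region": regions[i]} for i in range(225)]
eye = list(range(0, 40)); nose = list(range(40, 80)); mouth = list(range(80, 150))
subsets = {
    "21": eye[:5] + nose[:5] + mouth[:11],
    "50": eye[:13] + nose[:13] + mouth[:24],
    "91": eye[:24] + nose[:23] + mouth[:44],
    "140": eye[:40] + nose[:40] + mouth[:60],
}
dense = {
    "name": "dense-225",
    "n_landmarks": 478,
    "midline_indices": list(range(20)),
    "pairs": pairs,
    "subsets": subsets,
}
(out / "dense-225.json").write_text(json.dumps(dense, indent=1))

# ---- sparse-29 / sparse-21: canonical 68-point correspondence ----
# "left" is image-left (smaller x). Jaw pairs last so the contour-free
# subset is ordinals 0..20.
def p(l, r, g):
    return {"left": l, "right": r, "region": g}

brow = [p(17, 26, "eye"), p(18, 25, "eye"), p(19, 24, "eye"), p(20, 23, "eye"), p(21, 22, "eye")]
eye68 = [p(36, 45, "eye"), p(37, 44, "eye"), p(38, 43, "eye"), p(39, 42, "eye"), p(41, 46, "eye"), p(40, 47, "eye")]
nose68 = [p(31, 35, "nose"), p(32, 34, "nose")]
mouth_outer = [p(48, 54, "mouth"), p(49, 53, "mouth"), p(50, 52, "mouth"), p(59, 55, "mouth"), p(58, 56, "mouth")]
mouth_inner = [p(60, 64, "mouth"), p(61, 63, "mouth"), p(67, 65, "mouth")]
jaw = [p(i, 16 - i, "other") for i in range(8)]
pairs29 = brow + eye68 + nose68 + mouth_outer + mouth_inner + jaw
midline68 = [8, 27, 28, 29, 30, 33]  # chin + nose bridge/tip; mouth-axis 51,57,62,66 excluded
sparse29 = {
    "name": "sparse-29",
    "n_landmarks": 68,
    "midline_indices": midline68,
    "pairs": pairs29,
    "subsets": {"21": list(range(21))},
}
(out / "sparse-29.json").write_text(json.dumps(sparse29, indent=1))

sparse21 = {
    "name": "sparse-21",
    "n_landmarks": 68,
    "midline_indices": midline68,
    "pairs": pairs29[:21],
    "subsets": {},
}
(out / "sparse-21.json").write_text(json.dumps(sparse21, indent=1))

for f in out.glob("*.json"):
    print(f.name, f.stat().st_size, "bytes")
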