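{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "neuroprint seed file",
  "description": "A JSON list of seed strokes; each stroke is rasterized onto one axis-aligned slice and unioned into per-structure foreground/background seed sets.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["mode", "axis", "slice_index", "vertices", "role", "structure_id"],
    "properties": {
      "mode": {"enum": ["sketch", "polygon", "freedraw"]},
      "axis": {"enum": ["x", "y", "z"]},
      "slice_index": {"type": "integer", "minimum": 0},
      "vertices": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "array",
          "prefixItems": [{"type": "number"}, {"type": "number"}],
          "minItems": 2,
          "maxItems": 2
        },
        "description": "2-D points in voxel-center coordinates of the slice plane (in-plane axes in ascending order). sketch: polyline (>= 2 points); polygon: closed ring (>= 3); freedraw: explicit pixel set."
      },
      "role": {"enum": ["foreground", "background"]},
      "structure_id": {"type": "integer", "minimum": 1},
      "brush_radius": {"type": "integer", "minimum": 0, "default": 0,
                       "description": "Chebyshev dilation radius (sketch only)"}
    }
  }
}
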