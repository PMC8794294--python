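{
  "name": "bilateral_prefc_s1_default",
  "description": "Schematic 2D cap layout: 9 sources, 14 long-separation detectors (~30 mm), 9 short-separation detectors (8 mm, one per source). 24 long channels: 1-6 right PreFC, 7-12 left PreFC, 13-18 right S1, 19-24 left S1. Coordinates are in mm in an arbitrary flattened-cap frame (x>0 = right hemisphere, y>0 = frontal); they are schematic and used only for nearest-short-channel assignment, while per-channel path lengths use the nominal separations below.",
  "separation_long_mm": 30.0,
  "separation_short_mm": 8.0,
  "sources": [
    {"id": 1, "pos": [45, 100]},
    {"id": 2, "pos": [105, 100]},
    {"id": 3, "pos": [-45, 100]},
    {"id": 4, "pos": [-105, 100]},
    {"id": 5, "pos": [45, -40]},
    {"id": 6, "pos": [105, -40]},
    {"id": 7, "pos": [-45, -40]},
    {"id": 8, "pos": [-105, -40]},
    {"id": 9, "pos": [0, 140]}
  ],
  "long_detectors": [
    {"id": 1, "pos": [15, 100]},
    {"id": 2, "pos": [75, 100]},
    {"id": 3, "pos": [135, 100]},
    {"id": 4, "pos": [-15, 100]},
    {"id": 5, "pos": [-75, 100]},
    {"id": 6, "pos": [-135, 100]},
    {"id": 7, "pos": [15, -40]},
    {"id": 8, "pos": [75, -40]},
    {"id": 9, "pos": [135, -40]},
    {"id": 10, "pos": [-15, -40]},
    {"id": 11, "pos": [-75, -40]},
    {"id": 12, "pos": [-135, -40]},
    {"id": 13, "pos": [0, 110]},
    {"id": 14, "pos": [0, -70]}
  ],
  "short_detectors": [
    {"id": 1, "source_id": 1, "pos": [45, 108]},
    {"id": 2, "source_id": 2, "pos": [105, 108]},
    {"id": 3, "source_id": 3, "pos": [-45, 108]},
    {"id": 4, "source_id": 4, "pos": [-105, 108]},
    {"id": 5, "source_id": 5, "pos": [45, -32]},
    {"id": 6, "source_id": 6, "pos": [105, -32]},
    {"id": 7, "source_id": 7, "pos": [-45, -32]},
    {"id": 8, "source_id": 8, "pos": [-105, -32]},
    {"id": 9, "source_id": 9, "pos": [0, 148]}
  ],
  "channels": [
    {"channel_id": 1,  "source_id": 1, "detector_id": 1,  "hemisphere": "right", "region": "PreFC", "roi": "medial_PFC"},
    {"channel_id": 2,  "source_id": 1, "detector_id": 2,  "hemisphere": "right", "region": "PreFC", "roi": "medial_PFC"},
    {"channel_id": 3,  "source_id": 2, "detector_id": 1,  "hemisphere": "right", "region": "PreFC", "roi": "lateral_preFC"},
    {"channel_id": 4,  "source_id": 1, "detector_id": 3,  "hemisphere": "right", "region": "PreFC", "roi": "lateral_preFC"},
    {"channel_id": 5,  "source_id": 2, "detector_id": 2,  "hemisphere": "right", "region": "PreFC", "roi": "lateral_FC"},
    {"channel_id": 6,  "source_id": 2, "detector_id": 3,  "hemisphere": "right", "region": "PreFC", "roi": "lateral_FC"},
    {"channel_id": 7,  "source_id": 3, "detector_id": 4,  "hemisphere": "left",  "region": "PreFC", "roi": "medial_PFC"},
    {"channel_id": 8,  "source_id": 3, "detector_id": 5,  "hemisphere": "left",  "region": "PreFC", "roi": "medial_PFC"},
    {"channel_id": 9,  "source_id": 4, "detector_id": 4,  "hemisphere": "left",  "region": "PreFC", "roi": "lateral_preFC"},
    {"channel_id": 10, "source_id": 3, "detector_id": 6,  "hemisphere": "left",  "region": "PreFC", "roi": "lateral_preFC"},
    {"channel_id": 11, "source_id": 4, "detector_id": 5,  "hemisphere": "left",  "region": "PreFC", "roi": "lateral_FC"},
    {"channel_id": 12, "source_id": 4, "detector_id": 6,  "hemisphere": "left",  "region": "PreFC", "roi": "lateral_FC"},
    {"channel_id": 13, "source_id": 5, "detector_id": 7,  "hemisphere": "right", "region": "S1", "roi": "superior_S1"},
    {"channel_id": 14, "source_id": 5, "detector_id": 8,  "hemisphere": "right", "region": "S1", "roi": "superior_S1"},
    {"channel_id": 15, "source_id": 6, "detector_id": 7,  "hemisphere": "right", "region": "S1", "roi": "central_S1"},
    {"channel_id": 16, "source_id": 5, "detector_id": 9,  "hemisphere": "right", "region": "S1", "roi": "central_S1"},
    {"channel_id": 17, "source_id": 6, "detector_id": 8,  "hemisphere": "right", "region": "S1", "roi": "inferior_S1"},
    {"channel_id": 18, "source_id": 6, "detector_id": 9,  "hemisphere": "right", "region": "S1", "roi": "inferior_S1"},
    {"channel_id": 19, "source_id": 7, "detector_id": 10, "hemisphere": "left",  "region": "S1", "roi": "superior_S1"},
    {"channel_id": 20, "source_id": 7, "detector_id": 11, "hemisphere": "left",  "region": "S1", "roi": "superior_S1"},
    {"channel_id": 21, "source_id": 8, "detector_id": 10, "hemisphere": "left",  "region": "S1", "roi": "central_S1"},
    {"channel_id": 22, "source_id": 7, "detector_id": 12, "hemisphere": "left",  "region": "S1", "roi": "central_S1"},
    {"channel_id": 23, "source_id": 8, "detector_id": 11, "hemisphere": "left",  "region": "S1", "roi": "inferior_S1"},
    {"channel_id": 24, "source_id": 8, "detector_id": 12, "hemisphere": "left",  "region": "S1", "roi": "inferior_S1"}
  ],
  "quality_regions": {
    "medial_prefc": [1, 2, 7, 8],
    "lateral_prefc": [3, 4, 9, 10],
    "somatosensory": [15, 16, 21, 22]
  }
}
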