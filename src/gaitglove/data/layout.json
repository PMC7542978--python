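{
  "labels": [
    "MCP_T", "PIP_T",
    "MCP_I", "PIP_I",
    "MCP_M", "PIP_M",
    "MCP_R", "PIP_R",
    "MCP_L", "PIP_L",
    "A1", "A2", "A3", "A4",
    "PArch", "Tcross",
    "P1", "P2", "P3", "P4", "P5",
    "QH_W", "QH_X", "QH_Y", "QH_Z",
    "QW_W", "QW_X", "QW_Y", "QW_Z"
  ],
  "roles": {
    "MCP_T": "thumb_bend_MCP",
    "PIP_T": "thumb_bend_IP",
    "MCP_I": "finger_bend_MCP",
    "MCP_M": "finger_bend_MCP",
    "MCP_R": "finger_bend_MCP",
    "MCP_L": "finger_bend_MCP",
    "PIP_I": "finger_bend_PIP",
    "PIP_M": "finger_bend_PIP",
    "PIP_R": "finger_bend_PIP",
    "PIP_L": "finger_bend_PIP",
    "A1": "abduction",
    "A2": "abduction",
    "A3": "abduction",
    "A4": "abduction",
    "PArch": "palm_arch",
    "Tcross": "thumb_cross",
    "P1": "pressure",
    "P2": "pressure",
    "P3": "pressure",
    "P4": "pressure",
    "P5": "pressure",
    "QH_W": "orientation",
    "QH_X": "orientation",
    "QH_Y": "orientation",
    "QH_Z": "orientation",
    "QW_W": "orientation",
    "QW_X": "orientation",
    "QW_Y": "orientation",
    "QW_Z": "orientation"
  },
  "relevant19": [
    "MCP_T", "PIP_T",
    "MCP_I", "PIP_I",
    "MCP_M", "PIP_M",
    "MCP_R", "PIP_R",
    "MCP_L", "PIP_L",
    "A1", "A2", "A3", "A4",
    "PArch", "Tcross",
    "P1", "P2", "P3"
  ],
  "graph12": [
    "MCP_T", "PIP_T",
    "MCP_I", "PIP_I",
    "MCP_M", "PIP_M",
    "MCP_R", "PIP_R",
    "MCP_L", "PIP_L",
    "PArch", "Tcross"
  ],
  "canonical_positive": [
    "Tcross",
    "MCP_I", "MCP_M", "MCP_R", "MCP_L",
    "PIP_I", "PIP_M", "PIP_R", "PIP_L"
  ],
  "frequency_groups": {
    "thumb": ["MCP_T", "PIP_T", "Tcross", "PArch"],
    "MCP": ["MCP_I", "MCP_M", "MCP_R", "MCP_L"],
    "PIP": ["PIP_I", "PIP_M", "PIP_R", "PIP_L"]
  }
}
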