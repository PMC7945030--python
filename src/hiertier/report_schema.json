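{
  "title": "hiertier study report",
  "type": "object",
  "required": ["manifest", "groups", "contrasts", "bh_cutoff"],
  "properties": {
    "manifest": {"type": "object", "required": ["version", "seed", "density", "config_hash"]},
    "groups": {"type": "object"},
    "contrasts": {"type": "array"},
    "bh_cutoff": {"type": ["number", "null"]}
  }
}
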