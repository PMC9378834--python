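{
 "name": "17-miRPairs",
 "vote_rule": "majority_reversed",
 "pairs": [
  {"a": "miR-6746-5p", "b": "miR-6887-5p", "stability": 0.7858},
  {"a": "miR-6794-5p", "b": "miR-6741-5p", "stability": 0.9162},
  {"a": "miR-1343-3p", "b": "miR-6741-5p", "stability": 0.7695},
  {"a": "miR-211-3p", "b": "miR-1249-5p", "stability": 0.8161},
  {"a": "miR-6717-5p", "b": "miR-6887-5p", "stability": 0.7520},
  {"a": "miR-211-3p", "b": "miR-665", "stability": 0.7066},
  {"a": "miR-650", "b": "miR-6736-5p", "stability": 0.7206},
  {"a": "miR-6800-5p", "b": "miR-642a-3p", "stability": 0.7066},
  {"a": "miR-6748-5p", "b": "miR-6736-5p", "stability": 0.7567},
  {"a": "miR-6746-5p", "b": "miR-7114-5p", "stability": 0.7101},
  {"a": "miR-711", "b": "miR-1249-5p", "stability": 0.8801},
  {"a": "miR-939-5p", "b": "miR-8071", "stability": 0.7392},
  {"a": "miR-6877-5p", "b": "miR-6741-5p", "stability": 0.7101},
  {"a": "miR-1224-5p", "b": "miR-6736-5p", "stability": 0.7299},
  {"a": "miR-760", "b": "miR-6779-5p", "stability": 0.7509},
  {"a": "miR-6769a-5p", "b": "miR-7114-5p", "stability": 0.7590},
  {"a": "miR-3162-5p", "b": "miR-6124", "stability": 0.7078}
 ]
}
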