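{
 "name": "13-miRPairs",
 "vote_rule": "majority_reversed",
 "pairs": [
  {"a": "miR-6893-5p", "b": "miR-1290", "stability": 0.981},
  {"a": "miR-6800-5p", "b": "miR-1275", "stability": 0.977},
  {"a": "miR-6800-5p", "b": "miR-1290", "stability": 0.987},
  {"a": "miR-7845-5p", "b": "miR-4787-3p", "stability": 0.954},
  {"a": "miR-6763-5p", "b": "miR-1238-5p", "stability": 0.951},
  {"a": "miR-6784-5p", "b": "miR-5100", "stability": 0.977},
  {"a": "miR-3620-5p", "b": "miR-1275", "stability": 0.965},
  {"a": "miR-7845-5p", "b": "miR-320a", "stability": 0.965},
  {"a": "miR-6800-5p", "b": "miR-296-5p", "stability": 0.974},
  {"a": "miR-760", "b": "miR-665", "stability": 0.980},
  {"a": "miR-6089", "b": "miR-4532", "stability": 0.959},
  {"a": "miR-6786-5p", "b": "miR-3663-3p", "stability": 0.956},
  {"a": "miR-6794-5p", "b": "miR-1290", "stability": 0.951}
 ]
}
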