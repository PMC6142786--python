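{
 "domain_name": "EEG-based automatic sleep staging",
 "categories": [
  "EEG",
  "Sleep"
 ],
 "classes": {
  "participants": "EEG",
  "electrodes": "EEG",
  "features": "EEG",
  "sleep staging": "Sleep",
  "staging rules": "Sleep"
 },
 "instances": {
  "Fpz-Cz": "electrodes",
  "Pz-Oz": "electrodes",
  "six-state": "staging rules",
  "five-state": "staging rules",
  "four-state": "staging rules",
  "three-state": "staging rules",
  "two-state": "staging rules"
 },
 "object_properties": [],
 "data_properties": []
}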