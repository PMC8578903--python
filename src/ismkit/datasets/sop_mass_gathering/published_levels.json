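{
  "levels": {
    "I": [6, 7, 8, 10],
    "II": [2, 5, 9, 11],
    "III": [3, 4],
    "IV": [1]
  },
  "iteration_1": {
    "1": {"reachability": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 7], "intersection": [1, 7], "leveled": false},
    "2": {"reachability": [2, 3, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 9, 10, 11], "intersection": [2, 3, 5, 6, 7, 9, 10, 11], "leveled": false},
    "3": {"reachability": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 9], "intersection": [2, 3, 4, 5, 6, 7, 9], "leveled": false},
    "4": {"reachability": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 3, 4, 5, 6, 7, 9, 10, 11], "intersection": [3, 4, 5, 6, 7, 9, 10, 11], "leveled": false},
    "5": {"reachability": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 9, 10, 11], "intersection": [2, 3, 4, 5, 6, 7, 9, 10, 11], "leveled": false},
    "6": {"reachability": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "intersection": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "leveled": true},
    "7": {"reachability": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "intersection": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "leveled": true},
    "8": {"reachability": [6, 7, 8, 10], "antecedent": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "intersection": [6, 7, 8, 10], "leveled": true},
    "9": {"reachability": [2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 9, 10, 11], "intersection": [2, 3, 4, 5, 6, 7, 9, 10, 11], "leveled": false},
    "10": {"reachability": [2, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11], "intersection": [2, 4, 5, 6, 7, 8, 9, 10, 11], "leveled": true},
    "11": {"reachability": [2, 4, 5, 6, 7, 8, 9, 10, 11], "antecedent": [1, 2, 3, 4, 5, 6, 7, 9, 10, 11], "intersection": [2, 4, 5, 6, 7, 9, 10, 11], "leveled": false}
  }
}
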