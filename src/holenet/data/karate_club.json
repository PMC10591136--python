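{
 "directed": false,
 "nodes": [
  {
   "id": 0,
   "attrs": {}
  },
  {
   "id": 1,
   "attrs": {}
  },
  {
   "id": 2,
   "attrs": {}
  },
  {
   "id": 3,
   "attrs": {}
  },
  {
   "id": 4,
   "attrs": {}
  },
  {
   "id": 5,
   "attrs": {}
  },
  {
   "id": 6,
   "attrs": {}
  },
  {
   "id": 7,
   "attrs": {}
  },
  {
   "id": 8,
   "attrs": {}
  },
  {
   "id": 9,
   "attrs": {}
  },
  {
   "id": 10,
   "attrs": {}
  },
  {
   "id": 11,
   "attrs": {}
  },
  {
   "id": 12,
   "attrs": {}
  },
  {
   "id": 13,
   "attrs": {}
  },
  {
   "id": 14,
   "attrs": {}
  },
  {
   "id": 15,
   "attrs": {}
  },
  {
   "id": 16,
   "attrs": {}
  },
  {
   "id": 17,
   "attrs": {}
  },
  {
   "id": 18,
   "attrs": {}
  },
  {
   "id": 19,
   "attrs": {}
  },
  {
   "id": 20,
   "attrs": {}
  },
  {
   "id": 21,
   "attrs": {}
  },
  {
   "id": 22,
   "attrs": {}
  },
  {
   "id": 23,
   "attrs": {}
  },
  {
   "id": 24,
   "attrs": {}
  },
  {
   "id": 25,
   "attrs": {}
  },
  {
   "id": 26,
   "attrs": {}
  },
  {
   "id": 27,
   "attrs": {}
  },
  {
   "id": 28,
   "attrs": {}
  },
  {
   "id": 29,
   "attrs": {}
  },
  {
   "id": 30,
   "attrs": {}
  },
  {
   "id": 31,
   "attrs": {}
  },
  {
   "id": 32,
   "attrs": {}
  },
  {
   "id": 33,
   "attrs": {}
  }
 ],
 "edges": [
  {
   "u": 0,
   "v": 1,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 2,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 3,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 4,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 5,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 6,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 7,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 8,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 10,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 11,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 12,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 13,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 17,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 19,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 21,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 0,
   "v": 31,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 2,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 3,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 7,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 13,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 17,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 19,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 21,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 1,
   "v": 30,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 3,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 7,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 8,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 9,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 13,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 27,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 28,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 2,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 3,
   "v": 7,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 3,
   "v": 12,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 3,
   "v": 13,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 4,
   "v": 6,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 4,
   "v": 10,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 5,
   "v": 6,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 5,
   "v": 10,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 5,
   "v": 16,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 6,
   "v": 16,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 8,
   "v": 30,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 8,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 8,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 9,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 13,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 14,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 14,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 15,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 15,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 18,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 18,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 19,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 20,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 20,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 22,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 22,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 23,
   "v": 25,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 23,
   "v": 27,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 23,
   "v": 29,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 23,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 23,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 24,
   "v": 25,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 24,
   "v": 27,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 24,
   "v": 31,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 25,
   "v": 31,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 26,
   "v": 29,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 26,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 27,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 28,
   "v": 31,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 28,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 29,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 29,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 30,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 30,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 31,
   "v": 32,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 31,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  },
  {
   "u": 32,
   "v": 33,
   "weight": 1.0,
   "attrs": {}
  }
 ]
}
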