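{
 "type": "FeatureCollection",
 "features": [
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      0.0,
      0.0
     ],
     [
      100.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h0_0",
    "length": 100.0,
    "u": "n0_0",
    "v": "n0_1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      100.0,
      0.0
     ],
     [
      200.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h0_1",
    "length": 100.0,
    "u": "n0_1",
    "v": "n0_2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      0.0,
      100.0
     ],
     [
      100.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h1_0",
    "length": 100.0,
    "u": "n1_0",
    "v": "n1_1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      100.0,
      100.0
     ],
     [
      200.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h1_1",
    "length": 100.0,
    "u": "n1_1",
    "v": "n1_2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      0.0,
      200.0
     ],
     [
      100.0,
      200.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h2_0",
    "length": 100.0,
    "u": "n2_0",
    "v": "n2_1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      100.0,
      200.0
     ],
     [
      200.0,
      200.0
     ]
    ]
   },
   "properties": {
    "edge_id": "h2_1",
    "length": 100.0,
    "u": "n2_1",
    "v": "n2_2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      0.0,
      0.0
     ],
     [
      0.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v0_0",
    "length": 100.0,
    "u": "n0_0",
    "v": "n1_0"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      100.0,
      0.0
     ],
     [
      100.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v0_1",
    "length": 100.0,
    "u": "n0_1",
    "v": "n1_1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      200.0,
      0.0
     ],
     [
      200.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v0_2",
    "length": 100.0,
    "u": "n0_2",
    "v": "n1_2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      0.0,
      100.0
     ],
     [
      0.0,
      200.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v1_0",
    "length": 100.0,
    "u": "n1_0",
    "v": "n2_0"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      100.0,
      100.0
     ],
     [
      100.0,
      200.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v1_1",
    "length": 100.0,
    "u": "n1_1",
    "v": "n2_1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      200.0,
      100.0
     ],
     [
      200.0,
      200.0
     ]
    ]
   },
   "properties": {
    "edge_id": "v1_2",
    "length": 100.0,
    "u": "n1_2",
    "v": "n2_2"
   }
  }
 ]
}
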