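{
 "type": "FeatureCollection",
 "features": [
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
      150.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "d1a",
    "length": 111.80339887498948,
    "u": "a1",
    "v": "b1"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      150.0,
      100.0
     ],
     [
      200.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "d1b",
    "length": 111.80339887498948,
    "u": "b1",
    "v": "a2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      300.0,
      0.0
     ],
     [
      350.0,
      100.0
     ]
    ]
   },
   "properties": {
    "edge_id": "d2a",
    "length": 111.80339887498948,
    "u": "a3",
    "v": "b2"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      350.0,
      100.0
     ],
     [
      400.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "d2b",
    "length": 111.80339887498948,
    "u": "b2",
    "v": "a4"
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
      100.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "m0",
    "length": 100.0,
    "u": "a0",
    "v": "a1"
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
    "edge_id": "m1",
    "length": 100.0,
    "u": "a1",
    "v": "a2"
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
      300.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "m2",
    "length": 100.0,
    "u": "a2",
    "v": "a3"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      300.0,
      0.0
     ],
     [
      400.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "m3",
    "length": 100.0,
    "u": "a3",
    "v": "a4"
   }
  },
  {
   "type": "Feature",
   "geometry": {
    "type": "LineString",
    "coordinates": [
     [
      400.0,
      0.0
     ],
     [
      500.0,
      0.0
     ]
    ]
   },
   "properties": {
    "edge_id": "m4",
    "length": 100.0,
    "u": "a4",
    "v": "a5"
   }
  }
 ]
}
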