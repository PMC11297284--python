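{
 "0": 0.018666098852875512,
 "1": 0.024812461313142374,
 "2": 0.05462977283831261,
 "3": 0.046308122929443,
 "4": 0.04901960784313726,
 "5": 0.05264639258925524,
 "6": 0.038078668546928984,
 "7": 0.05859764299410733,
 "8": 0.017675741765231255,
 "9": 0.04807692307692307,
 "10": 0.021319196860522912,
 "11": 0.02988774374675665,
 "12": 0.05095966405190803,
 "13": 0.03493563529823768,
 "14": 0.0729166666666668,
 "15": 0.025173504046774663,
 "16": 0.048275929810019824,
 "17": 0.06227834787373149,
 "18": 0.01822832000202111,
 "19": 0.03139534883720928,
 "20": 0.03166503000993912,
 "21": 0.042702017264098995,
 "22": 0.048366491931933854,
 "23": 0.025130497686061792,
 "24": 0.027777777777777762,
 "25": 0.044523745143791454,
 "26": 0.0335238240974767,
 "27": 0.08309779830963493,
 "28": 0.01816780392545795,
 "29": 0.04268292682926829,
 "30": 0.024748978958501297,
 "31": 0.05140757694970821,
 "32": 0.05758650544679061,
 "33": 0.01595066083067752,
 "34": 0.04230769230769227,
 "35": 0.022819040383738855,
 "36": 0.051531126501946765,
 "37": 0.04953550219791017,
 "38": 0.02354794239562419,
 "39": 0.03877551020408161,
 "40": 0.03850089882539808,
 "41": 0.03476056929183346,
 "42": 0.044392522048364226,
 "43": 0.01889730072312413,
 "44": 0.05454545454545455,
 "45": 0.029070552933426204,
 "46": 0.02949509409974289,
 "47": 0.052509486536084005,
 "48": 0.019741468106653892,
 "49": 0.045955882352941235,
 "two_point_50_50": 0.25,
 "uniform_grid_50": 0.010000000000000007
}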