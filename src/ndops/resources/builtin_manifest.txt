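# Built-in plugin manifest.
# One descriptor per line: kind <TAB> id <TAB> priority <TAB> module:attr
# Services
service.types	types	0	ndops.types:TypeService
service.convert	convert	0	ndops.convert:ConvertService
service.ops	ops	0	ndops.ops.engine:OpService
service.modules	modules	0	ndops.modules:ModuleService
service.io	io	0	ndops.io.formats:IOService
# Sample types
sampletype	uint1	0	ndops.types:UINT1
sampletype	uint2	0	ndops.types:UINT2
sampletype	uint4	0	ndops.types:UINT4
sampletype	uint8	0	ndops.types:UINT8
sampletype	uint12	0	ndops.types:UINT12
sampletype	uint16	0	ndops.types:UINT16
sampletype	uint32	0	ndops.types:UINT32
sampletype	uint64	0	ndops.types:UINT64
sampletype	uint128	0	ndops.types:UINT128
sampletype	int8	0	ndops.types:INT8
sampletype	int16	0	ndops.types:INT16
sampletype	int32	0	ndops.types:INT32
sampletype	int64	0	ndops.types:INT64
sampletype	float32	0	ndops.types:FLOAT32
sampletype	float64	0	ndops.types:FLOAT64
sampletype	complex-float32	0	ndops.types:COMPLEX_FLOAT32
sampletype	complex-float64	0	ndops.types:COMPLEX_FLOAT64
sampletype	argb32	0	ndops.types:ARGB32
sampletype	boolean-bit	0	ndops.types:BOOLEAN_BIT
sampletype	unbounded-int	0	ndops.types:UNBOUNDED_INTEGER
sampletype	unbounded-decimal	0	ndops.types:UNBOUNDED_DECIMAL_T
# Converters
converter	convert.str-to-float	10	ndops.convert:STR_TO_FLOAT
converter	convert.str-to-int	20	ndops.convert:STR_TO_INT
converter	convert.str-to-bool	10	ndops.convert:STR_TO_BOOL
converter	convert.int-to-float	100	ndops.convert:INT_TO_FLOAT
converter	convert.float-to-int	5	ndops.convert:FLOAT_TO_INT
converter	convert.float-to-complex	50	ndops.convert:FLOAT_TO_COMPLEX
converter	convert.int-to-str	10	ndops.convert:INT_TO_STR
converter	convert.float-to-str	10	ndops.convert:FLOAT_TO_STR
converter	convert.image-to-dataset	10	ndops.convert:IMAGE_TO_DATASET
converter	convert.dataset-to-image	10	ndops.convert:DATASET_TO_IMAGE
# Ops
op	math.add#img-img	0	ndops.ops.builtins:MATH_ADD_IMG_IMG
op	math.add#img-const	0	ndops.ops.builtins:MATH_ADD_IMG_CONST
op	math.add#img-img-array	0	ndops.ops.builtins:MATH_ADD_IMG_IMG_ARRAY
op	math.add#img-const-array	0	ndops.ops.builtins:MATH_ADD_IMG_CONST_ARRAY
op	math.add#scalar	0	ndops.ops.builtins:MATH_ADD_SCALAR
op	math.sub#img-img	0	ndops.ops.builtins:MATH_SUB_IMG_IMG
op	math.sub#img-const	0	ndops.ops.builtins:MATH_SUB_IMG_CONST
op	math.sub#img-img-array	0	ndops.ops.builtins:MATH_SUB_IMG_IMG_ARRAY
op	math.sub#img-const-array	0	ndops.ops.builtins:MATH_SUB_IMG_CONST_ARRAY
op	math.sub#scalar	0	ndops.ops.builtins:MATH_SUB_SCALAR
op	math.mul#img-img	0	ndops.ops.builtins:MATH_MUL_IMG_IMG
op	math.mul#img-const	0	ndops.ops.builtins:MATH_MUL_IMG_CONST
op	math.mul#img-img-array	0	ndops.ops.builtins:MATH_MUL_IMG_IMG_ARRAY
op	math.mul#img-const-array	0	ndops.ops.builtins:MATH_MUL_IMG_CONST_ARRAY
op	math.mul#scalar	0	ndops.ops.builtins:MATH_MUL_SCALAR
op	math.div#img-img	0	ndops.ops.builtins:MATH_DIV_IMG_IMG
op	math.div#img-const	0	ndops.ops.builtins:MATH_DIV_IMG_CONST
op	math.div#img-img-array	0	ndops.ops.builtins:MATH_DIV_IMG_IMG_ARRAY
op	math.div#img-const-array	0	ndops.ops.builtins:MATH_DIV_IMG_CONST_ARRAY
op	math.div#scalar	0	ndops.ops.builtins:MATH_DIV_SCALAR
op	math.sqrt#img	0	ndops.ops.builtins:MATH_SQRT_IMG
op	math.sqrt#img-array	0	ndops.ops.builtins:MATH_SQRT_IMG_ARRAY
op	math.sqrt#scalar	0	ndops.ops.builtins:MATH_SQRT_SCALAR
op	math.identity#scalar	0	ndops.ops.builtins:MATH_IDENTITY_SCALAR
op	filter.gauss#separable	0	ndops.ops.builtins:FILTER_GAUSS
op	image.dog#chained	0	ndops.ops.builtins:IMAGE_DOG
op	stats.sum#whole	0	ndops.ops.builtins:STATS_SUM
op	stats.size#whole	0	ndops.ops.builtins:STATS_SIZE
op	stats.min#whole	0	ndops.ops.builtins:STATS_MIN
op	stats.max#whole	0	ndops.ops.builtins:STATS_MAX
op	stats.mean#composed	0	ndops.ops.builtins:STATS_MEAN
op	stats.sum#roi	0	ndops.ops.builtins:STATS_SUM_ROI
op	stats.size#roi	0	ndops.ops.builtins:STATS_SIZE_ROI
op	stats.min#roi	0	ndops.ops.builtins:STATS_MIN_ROI
op	stats.max#roi	0	ndops.ops.builtins:STATS_MAX_ROI
op	stats.mean#roi	0	ndops.ops.builtins:STATS_MEAN_ROI
op	image.map#special-op	0	ndops.ops.builtins:IMAGE_MAP
op	script.eval#expr	0	ndops.ops.builtins:SCRIPT_EVAL
op	script.eval#expr-bindings	0	ndops.ops.builtins:SCRIPT_EVAL_BOUND
op	create.img#zeros	0	ndops.ops.builtins:CREATE_IMG
# Formats
format	pgm	0	ndops.io.formats:PGM_FORMAT
format	ppm	0	ndops.io.formats:PPM_FORMAT
# Module pre/post-processing chains
preprocessor	pre.provided-binder	100	ndops.modules:PROVIDED_BINDER
preprocessor	pre.persisted-defaults	90	ndops.modules:PERSISTED_DEFAULTS
preprocessor	pre.active-image	80	ndops.modules:ACTIVE_IMAGE_INJECTOR
preprocessor	pre.declared-defaults	70	ndops.modules:DECLARED_DEFAULTS
preprocessor	pre.required-check	60	ndops.modules:REQUIRED_CHECK
postprocessor	post.text-display	0	ndops.modules:TEXT_DISPLAY
postprocessor	post.object-registrar	10	ndops.modules:OBJECT_REGISTRAR
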